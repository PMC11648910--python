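"""Global least-squares fitting of exchange models to CEST profile sets.

Kinetic parameters (exchange rates, minor-state populations) are shared
across all spins and B1 fields, while each spin carries its own
minor-state shift differences (delta-omega, ppm), major-state shift, and
relaxation rates.  The optimizer is bounded trust-region least squares
(scipy ``least_squares``, method ``trf``) with optional seeded multi-start
restarts to guard against local minima in four-state fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize
import scipy.sparse

from foldcest.bloch import CESTProfile, SpinSystem, simulate_profile
from foldcest.exchange import KineticNetwork, make_ff_model

__all__ = [
    "Parameter",
    "ParameterSet",
    "FitResult",
    "make_parameter_set",
    "initials_from_truth",
    "residuals",
    "fit_model",
    "estimate_uncertainties",
    "compare_models",
]

logger = logging.getLogger(__name__)

MINOR_STATES = {
    "two_state": ("I2",),
    "three_state": ("I1", "I2"),
    "four_state": ("I1", "I2", "U"),
}

# default |delta_omega| bound in ppm per nucleus
DW_BOUND = {"15N": 15.0, "13C": 15.0, "1H": 3.0}


@dataclass
class Parameter:
    """One scalar fit parameter with box bounds and a fixed/free flag."""

    value: float
    vmin: float = -np.inf
    vmax: float = np.inf
    vary: bool = True

    def __post_init__(self):
        if not (self.vmin <= self.value <= self.vmax):
            raise ValueError(
                f"initial value {self.value} outside bounds "
                f"[{self.vmin}, {self.vmax}]")


@dataclass
class ParameterSet:
    """Named parameters for a global CEST fit.

    Global kinetic parameters use plain names (``kex_FI2``, ``p_I2``);
    per-spin parameters are suffixed with the spin id
    (``dw_I2__s0``, ``omega__s0``, ``r1__s0``, ``r2__s0``).
    ``spin_meta`` maps spin id -> nucleus, needed to rebuild SpinSystem
    objects during simulation.
    """

    level: str
    params: dict[str, Parameter] = field(default_factory=dict)
    spin_meta: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            level=self.level,
            params={k: replace(v) for k, v in self.params.items()},
            spin_meta=dict(self.spin_meta),
        )

    # -- vector interface for the optimizer ---------------------------------
    @property
    def free_names(self) -> list[str]:
        return [k for k, p in self.params.items() if p.vary]

    def free_vector(self) -> np.ndarray:
        return np.array([self.params[k].value for k in self.free_names])

    def free_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.params[k].vmin for k in self.free_names])
        hi = np.array([self.params[k].vmax for k in self.free_names])
        return lo, hi

    def with_vector(self, x: np.ndarray) -> "ParameterSet":
        out = self.copy()
        for name, value in zip(self.free_names, x):
            out.params[name].value = float(value)
        return out

    def value(self, name: str) -> float:
        return self.params[name].value

    # -- model reconstruction ------------------------------------------------
    def kinetics(self) -> dict[str, float]:
        return {k: p.value for k, p in self.params.items()
                if k.startswith("kex_") or k.startswith("p_")}

    def network(self, temperature: float = 283.15) -> KineticNetwork:
        return make_ff_model(self.level, self.kinetics(), temperature=temperature)

    def spin(self, spin_id: str) -> SpinSystem:
        if spin_id not in self.spin_meta:
            raise ValueError(f"no parameters registered for spin {spin_id!r}")
        dw = {state: self.params[f"dw_{state}__{spin_id}"].value
              for state in MINOR_STATES[self.level]}
        return SpinSystem(
            spin_id=spin_id,
            nucleus=self.spin_meta[spin_id],
            omega_major=self.params[f"omega__{spin_id}"].value,
            delta_omega=dw,
            r1=self.params[f"r1__{spin_id}"].value,
            r2=self.params[f"r2__{spin_id}"].value,
        )


def make_parameter_set(
    level: str,
    profiles: list[CESTProfile],
    kinetics: dict[str, float],
    dw: dict[str, dict[str, float]],
    omega: dict[str, float],
    r1: float | dict[str, float] = 2.0,
    r2: float | dict[str, float] = 20.0,
    vary_relaxation: bool = False,
    kex_max: float = 5e4,
    p_max: float = 0.5,
) -> ParameterSet:
    """Assemble a ParameterSet covering every spin present in ``profiles``.

    ``kinetics`` supplies initial exchange rates (``kex_*``, s^-1) and
    minor populations (``p_*``, fractions); ``dw[spin][state]`` the initial
    shift differences in ppm; ``omega[spin]`` the major-state shift in ppm.
    R1/R2 may be a single value or per-spin; with ``vary_relaxation`` False
    they are held fixed at the given values.  Minor-state populations are
    bounded in (0, ``p_max``) and rates in (0, ``kex_max``).
    """
    pset = ParameterSet(level=level)
    for name, value in kinetics.items():
        if name.startswith("kex_"):
            pset.params[name] = Parameter(value, 1e-3, kex_max)
        elif name.startswith("p_"):
            pset.params[name] = Parameter(value, 1e-6, p_max)
        else:
            raise ValueError(f"unknown kinetic parameter {name!r}")

    spin_ids = []
    for prof in profiles:
        if prof.spin_id not in spin_ids:
            spin_ids.append(prof.spin_id)
            pset.spin_meta[prof.spin_id] = prof.experiment.nucleus

    def _per_spin(val, sid):
        return val[sid] if isinstance(val, dict) else val

    for sid in spin_ids:
        nucleus = pset.spin_meta[sid]
        bound = DW_BOUND[nucleus]
        if sid not in dw or sid not in omega:
            raise ValueError(f"spin {sid!r} missing dw/omega initials")
        for state in MINOR_STATES[level]:
            if state not in dw[sid]:
                raise ValueError(f"spin {sid!r} missing dw for state {state!r}")
            pset.params[f"dw_{state}__{sid}"] = Parameter(
                dw[sid][state], -bound, bound)
        pset.params[f"omega__{sid}"] = Parameter(
            omega[sid], omega[sid] - 10.0, omega[sid] + 10.0)
        pset.params[f"r1__{sid}"] = Parameter(
            _per_spin(r1, sid), 0.01, 100.0, vary=vary_relaxation)
        pset.params[f"r2__{sid}"] = Parameter(
            _per_spin(r2, sid), 0.1, 1000.0, vary=vary_relaxation)
    return pset


def initials_from_truth(truth: dict, profiles: list[CESTProfile],
                        level: str | None = None, perturb: float = 0.0,
                        seed: int = 0, vary_relaxation: bool = False,
                        omega_jitter: float = 0.3) -> ParameterSet:
    """Initial ParameterSet built from a ground-truth dictionary.

    ``truth`` follows the synthetic-data sidecar layout: a ``kinetics``
    table plus per-spin ``spins`` entries with ``omega_major``, ``r1``,
    ``r2`` and ``dw_<state>`` values.  With ``perturb`` > 0 every kinetic
    rate/population and every shift difference is multiplied by a seeded
    uniform factor in [1 - perturb, 1 + perturb]; major-state shifts get
    additive uniform jitter of up to ``omega_jitter`` ppm (a relative
    perturbation of an absolute shift would be physically meaningless).
    """
    if level is None:
        level = truth["scenario"]["level"]
    rng = np.random.default_rng(seed)

    def wobble(x):
        return x * (1.0 + perturb * rng.uniform(-1.0, 1.0)) if perturb else x

    kinetics = {k: wobble(v) for k, v in truth["kinetics"].items()
                if k.startswith("kex_") or k.startswith("p_")}
    needed = MINOR_STATES[level]
    missing_kin = [f"p_{s}" for s in needed if f"p_{s}" not in kinetics]
    if missing_kin:
        raise ValueError(f"truth lacks kinetics for level {level!r}: {missing_kin}")

    dw, omega, r1, r2 = {}, {}, {}, {}
    for sid, rec in truth["spins"].items():
        dw[sid] = {s: wobble(rec[f"dw_{s}"]) for s in needed}
        omega[sid] = rec["omega_major"] + (
            rng.uniform(-omega_jitter, omega_jitter) if perturb else 0.0)
        r1[sid] = rec["r1"]
        r2[sid] = rec["r2"]
    return make_parameter_set(level, profiles, kinetics, dw, omega,
                              r1=r1, r2=r2, vary_relaxation=vary_relaxation)


def residuals(params: ParameterSet, profiles: list[CESTProfile],
              level: str | None = None) -> np.ndarray:
    """Concatenated weighted residuals (observed - simulated) / error.

    Profiles without errors are weighted uniformly (error = 1).
    """
    if level is not None and level != params.level:
        raise ValueError(
            f"requested level {level!r} != parameter set level {params.level!r}")
    temperature = profiles[0].experiment.temperature + 273.15
    network = params.network(temperature=temperature)
    out = []
    for prof in profiles:
        spin = params.spin(prof.spin_id)
        sim = simulate_profile(spin, network, prof.experiment)
        err = prof.errors if prof.errors is not None else 1.0
        out.append((prof.intensities - sim.intensities) / err)
    return np.concatenate(out)


@dataclass
class FitResult:
    """Outcome of a global fit: best parameters, quality, diagnostics."""

    level: str
    params: ParameterSet
    chi2: float
    chi2_red: float
    n_points: int
    n_free: int
    residual: np.ndarray
    per_profile_residuals: list[np.ndarray]
    success: bool
    n_evaluations: int
    stderr: dict[str, float] = field(default_factory=dict)
    jacobian: np.ndarray | None = None
    profiles: list[CESTProfile] | None = None
    message: str = ""

    @property
    def aic(self) -> float:
        """Akaike information criterion on the chi-square scale."""
        return self.chi2 + 2.0 * self.n_free

    def at_boundary(self, rel_tol: float = 1e-6) -> list[str]:
        """Names of free parameters pinned at a bound."""
        pinned = []
        for name in self.params.free_names:
            p = self.params.params[name]
            scale = max(abs(p.value), 1.0)
            if (np.isfinite(p.vmin) and abs(p.value - p.vmin) < rel_tol * scale) or \
               (np.isfinite(p.vmax) and abs(p.value - p.vmax) < rel_tol * scale):
                pinned.append(name)
        return pinned


def _split_per_profile(vec: np.ndarray, profiles: list[CESTProfile]) -> list[np.ndarray]:
    sizes = [p.intensities.size for p in profiles]
    return list(np.split(vec, np.cumsum(sizes)[:-1]))


def _jacobian_sparsity(pset: ParameterSet,
                       profiles: list[CESTProfile]) -> np.ndarray:
    """Residual/parameter dependence mask for grouped finite differences.

    Kinetic parameters touch every residual; a per-spin parameter
    (``..__<spin_id>``) touches only that spin's profile blocks.  The
    mask lets the optimizer difference all same-role per-spin columns in
    one evaluation, which dominates the fit runtime for many-spin data.
    """
    names = pset.free_names
    n_points = sum(p.intensities.size for p in profiles)
    mask = np.zeros((n_points, len(names)), dtype=bool)
    starts = np.concatenate([[0], np.cumsum(
        [p.intensities.size for p in profiles])])
    for col, name in enumerate(names):
        if "__" in name:
            sid = name.split("__", 1)[1]
            for k, prof in enumerate(profiles):
                if prof.spin_id == sid:
                    mask[starts[k]:starts[k + 1], col] = True
        else:
            mask[:, col] = True
    return mask


def fit_model(profiles: list[CESTProfile], level: str, initial: ParameterSet,
              n_starts: int = 5, restart_scale: float = 0.2, seed: int = 0,
              ftol: float = 1e-10, xtol: float = 1e-10, max_iter: int = 500,
              early_stop_cost: float = 1e-12) -> FitResult:
    """Bounded nonlinear least-squares global fit.

    ``n_starts`` seeded restarts perturb the free parameters by a relative
    ``restart_scale`` (log-uniform for positive-bounded parameters); the
    start with the lowest chi-square wins.  Restarts stop early once a fit
    reaches ``early_stop_cost`` (essentially exact, e.g. noiseless data).
    Deterministic for identical inputs and options.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    if initial.level != level:
        raise ValueError("initial parameter set level does not match")
    n_points = sum(p.intensities.size for p in profiles)
    n_free = len(initial.free_names)
    if n_free >= n_points:
        raise ValueError(f"{n_free} free parameters for {n_points} points")

    lo, hi = initial.free_bounds()
    x0 = initial.free_vector()
    rng = np.random.default_rng(seed)

    def objective(x):
        return residuals(initial.with_vector(x), profiles)

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            xs = x0
        else:
            xs = np.clip(x0 * (1.0 + restart_scale * rng.uniform(-1, 1, x0.size)),
                         lo + 1e-12, hi - 1e-12)
        sol = scipy.optimize.least_squares(
            objective, xs, bounds=(lo, hi), method="trf",
            ftol=ftol, xtol=xtol, gtol=1e-12, x_scale="jac",
            jac_sparsity=_jacobian_sparsity(initial, profiles),
            max_nfev=max_iter * (x0.size + 1))
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= early_stop_cost:
            break

    chi2 = float(2.0 * best.cost)
    dof = max(n_points - n_free, 1)
    res_vec = best.fun
    result = FitResult(
        level=level,
        params=initial.with_vector(best.x),
        chi2=chi2,
        chi2_red=chi2 / dof,
        n_points=n_points,
        n_free=n_free,
        residual=res_vec,
        per_profile_residuals=_split_per_profile(res_vec, profiles),
        success=bool(best.success),
        n_evaluations=int(best.nfev),
        jacobian=best.jac,
        profiles=profiles,
        message=str(best.message),
    )
    result.stderr = _covariance_stderr(result)
    return result


def _covariance_stderr(fit: FitResult) -> dict[str, float]:
    """Standard errors from the scaled inverse of J^T J.

    Parameters whose information is singular get NaN and a warning.
    """
    if fit.jacobian is None:
        return {}
    J = fit.jacobian
    if scipy.sparse.issparse(J):
        J = J.toarray()
    names = fit.params.free_names
    JTJ = J.T @ J
    scale = fit.chi2_red if fit.chi2_red > 0 else 0.0
    try:
        cov = scale * np.linalg.inv(JTJ)
        diag = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix; covariance SEs undefined")
        # salvage what we can through the pseudo-inverse
        cov = scale * np.linalg.pinv(JTJ)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
    diag = np.where(diag >= 0, diag, np.nan)
    return {n: float(np.sqrt(d)) for n, d in zip(names, diag)}


def estimate_uncertainties(fit: FitResult, method: str = "covariance",
                           n_boot: int = 50, seed: int = 0) -> dict[str, float]:
    """Standard errors of the free parameters.

    ``covariance``: chi2_red-scaled inverse of J^T J from the converged fit.
    ``bootstrap``: parametric bootstrap -- synthetic datasets are drawn by
    adding Gaussian noise (per-point errors) to the best-fit simulation and
    refit from the best-fit parameters; SEs are the standard deviations of
    the refitted parameters over ``n_boot`` replicates.  Seeded, hence
    reproducible.
    """
    if method == "covariance":
        if not fit.success:
            warnings.warn("covariance SEs requested on an unconverged fit")
        return _covariance_stderr(fit)
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    if fit.profiles is None:
        raise ValueError("bootstrap requires the fitted profiles")
    for prof in fit.profiles:
        if prof.errors is None:
            raise ValueError("bootstrap requires per-point errors on every profile")

    rng = np.random.default_rng(seed)
    temperature = fit.profiles[0].experiment.temperature + 273.15
    network = fit.params.network(temperature=temperature)
    base = []
    for prof in fit.profiles:
        spin = fit.params.spin(prof.spin_id)
        base.append(simulate_profile(spin, network, prof.experiment).intensities)

    samples = []
    for _ in range(n_boot):
        fake = [
            CESTProfile(prof.experiment, prof.spin_id,
                        b + rng.normal(0.0, prof.errors), prof.errors)
            for prof, b in zip(fit.profiles, base)
        ]
        refit = fit_model(fake, fit.level, fit.params, n_starts=1,
                          seed=0, ftol=1e-8, xtol=1e-8)
        samples.append(refit.params.free_vector())
    sd = np.std(np.array(samples), axis=0, ddof=1)
    return {n: float(s) for n, s in zip(fit.params.free_names, sd)}


def compare_models(fits: list[FitResult]) -> list[dict]:
    """Rank fits of the same data by AIC = chi2 + 2 * n_free.

    Returns one record per fit with level, chi2_red, AIC and a ``best``
    flag on the lowest-AIC model.  Raises if the fits were not performed
    on identical data.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for other in fits[1:]:
        if other.n_points != ref.n_points:
            raise ValueError("fits must be performed on identical datasets")
        if ref.profiles is not None and other.profiles is not None:
            a = np.concatenate([p.intensities for p in ref.profiles])
            b = np.concatenate([p.intensities for p in other.profiles])
            if a.shape != b.shape or not np.allclose(a, b):
                raise ValueError("fits must be performed on identical datasets")
    table = [{
        "level": f.level,
        "chi2": f.chi2,
        "chi2_red": f.chi2_red,
        "n_free": f.n_free,
        "aic": f.aic,
        "best": False,
    } for f in fits]
    table[int(np.argmin([f.aic for f in fits]))]["best"] = True
    return table
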