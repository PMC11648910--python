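"""Free energies and urea m-values of states and transition states.

For a minor state K relative to the folded reference F the free-energy
difference follows from equilibrium populations,

    dG_FK = -R T ln(p_K / p_F)            [kJ/mol]

and for the transition state between K and L from the microscopic rate
k_KL (s^-1, from state K toward L) via a transition-state-theory-like
relation with an arbitrary prefactor C,

    dG_F-TSKL = -R T ln(p_K / p_F) - R T ln(k_KL / C),    C = 1e7 s^-1.

Detailed balance (p_K k_KL = p_L k_LK) makes the transition-state free
energy independent of which side it is computed from, and changing C
shifts every TS free energy by the same constant, leaving the m-values
untouched.  The urea m-value of a (transition) state J is minus the slope
of dG_FJ versus urea concentration, a proxy for the change in
solvent-exposed surface area relative to F.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from foldcest.exchange import KineticNetwork

__all__ = [
    "R_GAS",
    "TS_PREFACTOR",
    "UreaPoint",
    "MValueFit",
    "deltaG_state",
    "deltaG_transition",
    "fit_m_value",
    "m_value_profile",
    "delta_method_se",
]

logger = logging.getLogger(__name__)

R_GAS = 8.314  # J mol^-1 K^-1
TS_PREFACTOR = 1e7  # s^-1, arbitrary constant C in the TS free energy

#: Transition-state labels of the four-state folding topology, each with
#: the (source, destination) direction used to pick the microscopic rate.
#: The value is side-independent for a detailed-balanced network.
TS_DEFINITIONS = {
    "TS_UI1": ("U", "I1"),
    "TS_I1I2": ("I1", "I2"),
    "TS_I1F": ("I1", "F"),
    "TS_I2F": ("I2", "F"),
}


def deltaG_state(p_k: float, p_f: float, temperature: float) -> float:
    """Free energy of state K relative to F, in kJ/mol."""
    if p_k <= 0 or p_f <= 0:
        raise ValueError("populations must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 (Kelvin)")
    return -R_GAS * temperature * math.log(p_k / p_f) / 1000.0


def deltaG_transition(p_k: float, p_f: float, k_kl: float, temperature: float,
                      prefactor: float = TS_PREFACTOR) -> float:
    """Free energy of the K->L transition state relative to F, in kJ/mol."""
    if k_kl <= 0:
        raise ValueError("microscopic rate k_KL must be > 0")
    if prefactor <= 0:
        raise ValueError("prefactor C must be > 0")
    rt = R_GAS * temperature / 1000.0
    return deltaG_state(p_k, p_f, temperature) - rt * math.log(k_kl / prefactor)


@dataclass(frozen=True)
class UreaPoint:
    """A fitted exchange network at one urea concentration.

    ``dg_se`` optionally carries first-order-propagated standard errors of
    the free energies (kJ/mol), keyed by state or transition-state label;
    when present for every point of a series the m-value regression is
    weighted by 1/SE^2.
    """

    urea: float
    network: KineticNetwork
    dg_se: dict[str, float] | None = None

    def __post_init__(self):
        if self.urea < 0:
            raise ValueError("urea concentration must be >= 0")

    @property
    def temperature(self) -> float:
        return self.network.temperature


@dataclass
class MValueFit:
    """Linear fit of dG_FJ versus urea for one state or transition state."""

    target: str
    urea: np.ndarray
    dg: np.ndarray
    dg_se: np.ndarray | None
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float

    @property
    def m_value(self) -> float:
        """kJ mol^-1 M^-1; positive when the state is more solvent-exposed than F."""
        return -self.slope

    @property
    def m_value_se(self) -> float:
        return self.slope_se


def fit_m_value(points, target: str = "") -> MValueFit:
    """Fit dG = a + b * [urea]; the m-value is -b.

    ``points`` is a sequence of (urea, dG) or (urea, dG, SE) tuples.  With
    SEs present the regression is weighted by 1/SE^2, otherwise unweighted.
    """
    rows = [tuple(p) for p in points]
    if len(rows) < 2:
        raise ValueError("at least two urea points required")
    urea = np.array([r[0] for r in rows], dtype=float)
    dg = np.array([r[1] for r in rows], dtype=float)
    if np.unique(urea).size < 2:
        raise ValueError("at least two distinct urea concentrations required")
    ses = None
    if all(len(r) >= 3 and r[2] is not None for r in rows):
        ses = np.array([r[2] for r in rows], dtype=float)
        if np.any(ses <= 0):
            ses = None

    X = sm.add_constant(urea)
    if ses is not None:
        model = sm.WLS(dg, X, weights=1.0 / ses**2)
    else:
        model = sm.OLS(dg, X)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = model.fit()
        intercept, slope = res.params
        # with 2 points the line is exact and statsmodels reports nan SEs
        bse = np.asarray(res.bse)
    se_i, se_s = (float(x) if np.isfinite(x) else 0.0 for x in bse)
    return MValueFit(target=target, urea=urea, dg=dg, dg_se=ses,
                     slope=float(slope), intercept=float(intercept),
                     slope_se=se_s, intercept_se=se_i)


def _series(points: list[UreaPoint], target: str):
    """(urea, dG, SE) rows for one state or TS label across a urea series."""
    rows = []
    for pt in points:
        net = pt.network
        p_f = net.populations[0]
        T = net.temperature
        if target in TS_DEFINITIONS:
            src, dst = TS_DEFINITIONS[target]
            k = net.microscopic_rate(src, dst)
            if k <= 0:
                return None
            dg = deltaG_transition(net.population(src), p_f, k, T)
        else:
            dg = deltaG_state(net.population(target), p_f, T)
        se = pt.dg_se.get(target) if pt.dg_se else None
        rows.append((pt.urea, dg, se))
    return rows


def m_value_profile(points: list[UreaPoint],
                    targets: list[str] | None = None) -> list[MValueFit]:
    """m-values for every minor state and defined transition state.

    All points must share topology and temperature.  Transition states
    whose edge is absent from the network are omitted with a warning.
    The point order does not affect the result.
    """
    if len(points) < 2:
        raise ValueError("at least two urea points required")
    ref = points[0].network
    for pt in points[1:]:
        if pt.network.state_labels != ref.state_labels:
            raise ValueError("all networks must share the same states")
        if abs(pt.network.temperature - ref.temperature) > 1e-9:
            raise ValueError("all points must share one temperature; "
                             "mixing temperatures in an m-value fit is invalid")
    if targets is None:
        targets = list(ref.state_labels[1:]) + [
            ts for ts, (a, b) in TS_DEFINITIONS.items()
            if a in ref.state_labels and b in ref.state_labels]

    fits = []
    for target in targets:
        rows = _series(points, target)
        if rows is None:
            logger.warning("edge for %s absent from network; omitted", target)
            continue
        fits.append(fit_m_value(rows, target=target))
    return fits


def delta_method_se(func, values: dict[str, float], ses: dict[str, float],
                    rel_step: float = 1e-6) -> float:
    """First-order (delta-method) SE of ``func(values)``.

    ``func`` maps a parameter dict to a scalar; ``ses`` holds standard
    errors for a subset of the parameters (others are treated as exact).
    Gradients are central finite differences with relative step
    ``rel_step``; parameter covariances are neglected.
    """
    var = 0.0
    for name, se in ses.items():
        if name not in values or se == 0.0:
            continue
        h = rel_step * max(abs(values[name]), 1e-12)
        up = dict(values, **{name: values[name] + h})
        dn = dict(values, **{name: values[name] - h})
        grad = (func(up) - func(dn)) / (2.0 * h)
        var += (grad * se) ** 2
    return math.sqrt(var)
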