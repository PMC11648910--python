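"""Bloch-McConnell forward simulation of CEST profiles under N-state exchange.

A CEST experiment applies a weak radio-frequency (RF) field of strength B1
(expressed as a nutation frequency in Hz) at a series of offsets during a
saturation period T_EX.  When the RF is resonant with an exchanging minor
state, saturation is transferred to the observed major-state peak, carving
a "dip" into the intensity-vs-offset profile at the minor-state resonance.

The magnetization of N exchanging states is propagated with the augmented
(3N+1)-dimensional Bloch-McConnell matrix: per state a 3x3 Bloch block
(transverse relaxation R2, longitudinal relaxation R1, RF nutation coupling
z<->y at 2*pi*B1, x-y precession at the state's rotating-frame offset),
exchange coupling like components of different states with the microscopic
rate matrix, and a unit augmentation row/column carrying the
R1_i * p_i return-to-equilibrium terms.

Conventions
-----------
* RF phase is fixed along x, so nutation couples z and y.
* The observed intensity is M_z of the major (first) state only,
  normalized by its T_EX = 0 value p_major, i.e. I/I0 = M_z,F / p_F.
* Offsets are in Hz relative to the carrier; chemical shifts in ppm.
* Delta-omega values are signed, minor minus major, in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from foldcest.exchange import KineticNetwork, build_rate_matrix

__all__ = [
    "GYRO_RATIO",
    "SpinSystem",
    "CESTExperiment",
    "CESTProfile",
    "ppm_to_hz",
    "evolution_matrix",
    "propagate",
    "simulate_profile",
]

#: Gyromagnetic ratios relative to 1H.
GYRO_RATIO = {"1H": 1.0, "13C": 0.25145020, "15N": 0.10136767}


def ppm_to_hz(shift_ppm: float, nucleus: str, spectrometer_1h_freq: float) -> float:
    """Convert a chemical shift difference in ppm to Hz.

    ``spectrometer_1h_freq`` is the 1H Larmor frequency in MHz (e.g. 700
    for a 16.4 T magnet); the nucleus Larmor frequency is obtained from
    its gyromagnetic ratio relative to 1H.
    """
    try:
        gamma = GYRO_RATIO[nucleus]
    except KeyError:
        raise ValueError(
            f"unknown nucleus {nucleus!r}; supported: {sorted(GYRO_RATIO)}"
        ) from None
    return shift_ppm * spectrometer_1h_freq * gamma


@dataclass(frozen=True)
class SpinSystem:
    """One nucleus: major-state shift, minor-state shift differences, relaxation.

    ``delta_omega`` maps minor-state label -> signed shift difference
    (minor minus major) in ppm.  ``r1`` and ``r2`` map state label -> rate
    in s^-1; a plain float is broadcast to every state of the network the
    spin is simulated with.
    """

    spin_id: str
    nucleus: str
    omega_major: float
    delta_omega: dict[str, float]
    r1: dict[str, float] | float = 2.0
    r2: dict[str, float] | float = 20.0

    def __post_init__(self):
        if self.nucleus not in GYRO_RATIO:
            raise ValueError(f"unknown nucleus {self.nucleus!r}")

    def shift(self, state: str, major: str) -> float:
        """Absolute chemical shift (ppm) of this spin in ``state``."""
        if state == major:
            return self.omega_major
        if state not in self.delta_omega:
            raise ValueError(
                f"spin {self.spin_id!r} has no delta_omega for state {state!r}")
        return self.omega_major + self.delta_omega[state]

    def _rate(self, which: str, state: str) -> float:
        rates = self.r1 if which == "r1" else self.r2
        if isinstance(rates, dict):
            if state not in rates:
                raise ValueError(
                    f"spin {self.spin_id!r}: no {which} for state {state!r}")
            value = rates[state]
        else:
            value = rates
        if value <= 0:
            raise ValueError(f"{which} must be > 0, got {value}")
        return float(value)


@dataclass(frozen=True)
class CESTExperiment:
    """Acquisition metadata for one CEST series.

    B1 and offsets in Hz, T_EX in s, spectrometer 1H frequency in MHz,
    carrier in ppm, temperature in Celsius.  ``b1_inhomogeneity`` is the
    relative standard deviation of the B1 distribution (0 = ideal field).
    """

    b1: float
    t_ex: float
    spectrometer_1h_freq: float
    carrier: float
    offsets: np.ndarray
    nucleus: str = "15N"
    temperature: float = 10.0
    b1_inhomogeneity: float = 0.0

    def __post_init__(self):
        offs = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "offsets", offs)
        if self.b1 <= 0:
            raise ValueError("B1 must be > 0")
        if self.t_ex < 0:
            raise ValueError("T_EX must be >= 0")
        if not np.all(np.isfinite(offs)):
            raise ValueError("offsets must be finite")
        if len(np.unique(offs)) != len(offs):
            raise ValueError("offsets must be distinct")
        if self.b1_inhomogeneity < 0:
            raise ValueError("b1_inhomogeneity must be >= 0")


@dataclass(frozen=True)
class CESTProfile:
    """One (spin, B1) saturation profile: normalized intensities per offset."""

    experiment: CESTExperiment
    spin_id: str
    intensities: np.ndarray
    errors: np.ndarray | None = None

    def __post_init__(self):
        ints = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", ints)
        if ints.shape != self.experiment.offsets.shape:
            raise ValueError("intensities must match offsets in length")
        if self.errors is not None:
            errs = np.asarray(self.errors, dtype=float)
            object.__setattr__(self, "errors", errs)
            if errs.shape != ints.shape:
                raise ValueError("errors must match offsets in length")
            if np.any(errs <= 0):
                raise ValueError("errors must be > 0 when present")


def _state_frequencies(spin: SpinSystem, network: KineticNetwork,
                       experiment: CESTExperiment) -> np.ndarray:
    """Rotating-frame resonance (Hz from carrier) of the spin in each state."""
    major = network.state_labels[0]
    return np.array([
        ppm_to_hz(spin.shift(s, major) - experiment.carrier,
                  spin.nucleus, experiment.spectrometer_1h_freq)
        for s in network.state_labels
    ])


def _assemble(spin: SpinSystem, network: KineticNetwork, b1: float,
              offsets: np.ndarray, resonances: np.ndarray,
              m_eq: float = 1.0) -> np.ndarray:
    """Stack of augmented evolution matrices, one per offset.

    ``m_eq`` scales the thermal-equilibrium z-magnetization the augmented
    return term relaxes toward, in units of the prepared initial
    magnetization.  Profile simulation uses 0 (the prepared polarization,
    transferred from 1H, dwarfs the thermal value -- the standard CEST
    fitting convention, which gives the exp(-R1 T_EX) off-resonance
    baseline seen in measured profiles); the bare matrix defaults to 1 so
    that thermal equilibrium is exactly stationary without RF.
    Returns array of shape (n_offsets, 3N+1, 3N+1).
    """
    n = network.n_states
    dim = 3 * n + 1
    K = build_rate_matrix(network)
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    A = np.zeros((offsets.size, dim, dim))

    omega1 = 2.0 * np.pi * b1
    labels = network.state_labels
    for i, state in enumerate(labels):
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        r1 = spin._rate("r1", state)
        r2 = spin._rate("r2", state)
        domega = 2.0 * np.pi * (resonances[i] - offsets)  # per offset
        A[:, x, x] = -r2
        A[:, y, y] = -r2
        A[:, z, z] = -r1
        A[:, x, y] = -domega
        A[:, y, x] = domega
        A[:, y, z] = omega1
        A[:, z, y] = -omega1
        A[:, z, -1] = r1 * network.populations[i] * m_eq
        # exchange couples like components of all states
        for j in range(n):
            if K[i, j] != 0.0 or i == j:
                for c in range(3):
                    A[:, 3 * i + c, 3 * j + c] += K[i, j]
    return A


def evolution_matrix(spin: SpinSystem, network: KineticNetwork, b1: float,
                     offset: float, experiment: CESTExperiment | None = None,
                     carrier: float = 0.0,
                     spectrometer_1h_freq: float = 700.0) -> np.ndarray:
    """Augmented (3N+1) x (3N+1) Bloch-McConnell matrix at a single offset.

    When ``experiment`` is given its carrier and field are used; otherwise
    ``carrier`` (ppm) and ``spectrometer_1h_freq`` (MHz) apply.
    """
    if experiment is None:
        experiment = CESTExperiment(
            b1=max(b1, 1e-12), t_ex=0.0, spectrometer_1h_freq=spectrometer_1h_freq,
            carrier=carrier, offsets=np.array([offset]), nucleus=spin.nucleus)
    resonances = _state_frequencies(spin, network, experiment)
    return _assemble(spin, network, b1, np.array([offset]), resonances)[0]


def propagate(matrix: np.ndarray, initial: np.ndarray, t_ex: float) -> np.ndarray:
    """Return expm(matrix * t_ex) @ initial."""
    matrix = np.asarray(matrix, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if initial.shape != (matrix.shape[0],):
        raise ValueError("initial vector length must match matrix dimension")
    if t_ex == 0.0:
        return initial.copy()
    return scipy.linalg.expm(matrix * t_ex) @ initial


def _propagate_batch(A: np.ndarray, v: np.ndarray, t: float) -> np.ndarray:
    """exp(A_k t) @ v for a stack of matrices via batched eigendecomposition.

    Falls back to scipy's expm for any member whose eigenbasis is
    ill-conditioned (near-defective matrix).
    """
    w, V = np.linalg.eig(A)
    rhs = np.broadcast_to(v, w.shape)[..., None].copy()
    coeff = np.linalg.solve(V, rhs)[..., 0]
    out = np.einsum("kij,kj->ki", V, np.exp(w * t) * coeff).real

    cond = np.linalg.cond(V)
    bad = ~np.isfinite(cond) | (cond > 1e10)
    for k in np.nonzero(bad)[0]:
        out[k] = scipy.linalg.expm(A[k] * t) @ v
    return out


def _equilibrium_vector(network: KineticNetwork) -> np.ndarray:
    n = network.n_states
    v = np.zeros(3 * n + 1)
    v[2:3 * n:3] = network.populations
    v[-1] = 1.0
    return v


def simulate_profile(spin: SpinSystem, network: KineticNetwork,
                     experiment: CESTExperiment) -> CESTProfile:
    """Forward-simulate a normalized CEST profile I/I0 vs offset.

    Magnetization starts from the prepared state (M_z,i = p_i in units of
    the initial polarization), evolves for T_EX under RF saturation, and
    the major-state z-magnetization is read out and normalized by its
    T_EX = 0 value.  Longitudinal relaxation during T_EX decays toward a
    negligible thermal value (see ``_assemble``), so the off-resonance
    baseline is exp(-R1_F T_EX).  With a nonzero
    ``b1_inhomogeneity`` the profile is the Gaussian-weighted average over
    11 B1 values spanning +/- 2 standard deviations.
    """
    resonances = _state_frequencies(spin, network, experiment)
    v0 = _equilibrium_vector(network)
    p_major = network.populations[0]

    if experiment.b1_inhomogeneity > 0:
        sd = experiment.b1_inhomogeneity * experiment.b1
        grid = experiment.b1 + sd * np.linspace(-2.0, 2.0, 11)
        weights = np.exp(-0.5 * ((grid - experiment.b1) / sd) ** 2)
        weights /= weights.sum()
    else:
        grid = np.array([experiment.b1])
        weights = np.array([1.0])

    intensity = np.zeros(experiment.offsets.size)
    for b1, wt in zip(grid, weights):
        A = _assemble(spin, network, b1, experiment.offsets, resonances,
                      m_eq=0.0)
        if experiment.t_ex == 0.0:
            final = np.broadcast_to(v0, (A.shape[0], v0.size))
        else:
            final = _propagate_batch(A, v0, experiment.t_ex)
        intensity += wt * final[:, 2] / p_major  # M_z of major state
    return CESTProfile(experiment=experiment, spin_id=spin.spin_id,
                       intensities=intensity)
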