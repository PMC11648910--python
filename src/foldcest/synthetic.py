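"""Ground-truth scenarios and synthetic CEST datasets.

Four named scenarios cover the regimes the analysis pipeline must handle;
their kinetic ground truths are literature fit parameters for the
A17G FF domain folding network:

* ``A`` -- four-state folding network (F, I1, I2, U) at 10 C, amide 15N
  profiles at four B1 fields (26, 52.1, 104.1, 208.3 Hz).
* ``B`` -- two-state F <-> I2 exchange at 20 C in 20% glucose buffer,
  B1 = 26.4 and 52.9 Hz (glucose depletes I1 and U, isolating I2).
* ``C`` -- two-state F <-> I2 exchange for the S56P double-mutant
  construct at 20 C in 30% glucose: slow exchange, I2 heavily populated.
* ``D`` -- urea titration of the four-state network at 2.5 C, built so
  every state and transition-state free energy is exactly linear in urea
  with the literature m-values; used to exercise the m-value pipeline.

The Scenario D 0 M anchor uses the Scenario A populations and rates
(transplanted to 2.5 C).  The anchor choice shifts every free-energy
series by a constant and leaves all slopes -- hence all m-values --
untouched.  The transition state between I1 and I2 has no literature
m-value; a placeholder of 1.0 kJ/mol/M is used and flagged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from foldcest.bloch import CESTExperiment, CESTProfile, SpinSystem, ppm_to_hz, simulate_profile
from foldcest.exchange import KineticNetwork, make_ff_model
from foldcest.thermo import R_GAS, TS_DEFINITIONS, TS_PREFACTOR, UreaPoint, deltaG_state, deltaG_transition

__all__ = [
    "Scenario",
    "scenario",
    "make_spin_set",
    "generate_profiles",
    "urea_series",
    "SCENARIO_D_M_VALUES",
    "SCENARIO_D_UREA_GRID",
]

#: Literature state and transition-state m-values (kJ mol^-1 M^-1) used as
#: Scenario D ground truth.  TS_I1I2 is a placeholder (no reference value).
SCENARIO_D_M_VALUES = {
    "U": 6.6,
    "I1": 2.8,
    "I2": -0.1,
    "TS_UI1": 4.0,
    "TS_I1I2": 1.0,
    "TS_I1F": 2.1,
    "TS_I2F": 0.3,
}

SCENARIO_D_UREA_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: Default offset grids: (half-width in ppm, number of points) per nucleus.
#: Wide enough to cover the largest minor-state shift difference used by
#: the scenarios.
OFFSET_GRID = {"15N": (14.0, 61), "13C": (12.0, 61), "1H": (4.0, 61)}

#: Default carriers (ppm): amide 15N, aliphatic 13C, amide 1H regions.
CARRIER = {"15N": 119.0, "13C": 55.0, "1H": 8.3}

_SCENARIO_KINETICS = {
    "A": ("four_state", {
        "kex_FI1": 784.0, "kex_FI2": 406.0, "kex_I1I2": 1600.0,
        "kex_I1U": 11000.0, "p_I1": 0.0027, "p_I2": 0.0083, "p_U": 0.0016,
    }, 10.0, (26.0, 52.1, 104.1, 208.3)),
    "B": ("two_state", {"kex_FI2": 587.0, "p_I2": 0.021},
          20.0, (26.4, 52.9)),
    "C": ("two_state", {"kex_FI2": 41.4, "p_I2": 0.272},
          20.0, (12.5, 25.0)),
    "D": ("four_state", None, 2.5, (26.0, 52.1)),
}


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified synthetic study condition."""

    name: str
    level: str
    kinetics: dict[str, float]
    temperature_c: float
    b1_hz: tuple[float, ...]
    t_ex: float = 0.4
    spectrometer_1h_freq: float = 700.0
    nucleus: str = "15N"
    n_spins: int = 10
    noise_sd: float = 0.0
    seed: int = 0
    urea_grid: tuple[float, ...] | None = None

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15

    @property
    def carrier(self) -> float:
        return CARRIER[self.nucleus]

    def network(self) -> KineticNetwork:
        return make_ff_model(self.level, self.kinetics,
                             temperature=self.temperature_k)

    def experiments(self) -> list[CESTExperiment]:
        half, n = OFFSET_GRID[self.nucleus]
        half_hz = ppm_to_hz(half, self.nucleus, self.spectrometer_1h_freq)
        offsets = np.linspace(-half_hz, half_hz, n)
        return [
            CESTExperiment(b1=b1, t_ex=self.t_ex,
                           spectrometer_1h_freq=self.spectrometer_1h_freq,
                           carrier=self.carrier, offsets=offsets,
                           nucleus=self.nucleus, temperature=self.temperature_c)
            for b1 in self.b1_hz
        ]


def scenario(name: str, **overrides) -> Scenario:
    """Return one of the named ground-truth scenarios (A, B, C, D)."""
    if name not in _SCENARIO_KINETICS:
        raise ValueError(f"unknown scenario {name!r}; choose from A, B, C, D")
    level, kinetics, temp_c, b1 = _SCENARIO_KINETICS[name]
    kwargs = dict(name=name, level=level, temperature_c=temp_c, b1_hz=b1)
    if name == "D":
        kwargs["kinetics"] = dict(_SCENARIO_KINETICS["A"][1])  # 0 M anchor
        kwargs["urea_grid"] = SCENARIO_D_UREA_GRID
    else:
        kwargs["kinetics"] = dict(kinetics)
    kwargs.update(overrides)
    return Scenario(**kwargs)


def urea_series(scn: Scenario | None = None,
                urea_grid=None,
                m_values: dict[str, float] | None = None) -> list[UreaPoint]:
    """Four-state networks along a urea titration with exactly linear dG.

    Free energies of the minor states and transition states at each urea
    concentration are the 0 M anchor values minus m * [urea]; populations
    and exchange rates are reconstructed from them, so pushing the series
    back through the thermodynamic layer recovers every m-value exactly.
    """
    scn = scn or scenario("D")
    if scn.level != "four_state":
        raise ValueError("urea series requires a four-state scenario")
    urea_grid = tuple(urea_grid if urea_grid is not None
                      else (scn.urea_grid or SCENARIO_D_UREA_GRID))
    m_values = m_values or SCENARIO_D_M_VALUES
    T = scn.temperature_k
    rt = R_GAS * T / 1000.0  # kJ/mol

    anchor = scn.network()
    minors = anchor.state_labels[1:]
    p_f0 = anchor.populations[0]
    dg0 = {s: deltaG_state(anchor.population(s), p_f0, T) for s in minors}
    ts_dg0 = {}
    for ts, (src, dst) in TS_DEFINITIONS.items():
        k = anchor.microscopic_rate(src, dst)
        ts_dg0[ts] = deltaG_transition(anchor.population(src), p_f0, k, T)

    points = []
    for urea in urea_grid:
        dg = {s: dg0[s] - m_values[s] * urea for s in minors}
        ratio = {s: math.exp(-dg[s] / rt) for s in minors}
        p_f = 1.0 / (1.0 + sum(ratio.values()))
        pops = {s: ratio[s] * p_f for s in minors}

        kinetics = {f"p_{s}": pops[s] for s in minors}
        for ts, (src, dst) in TS_DEFINITIONS.items():
            ts_dg = ts_dg0[ts] - m_values[ts] * urea
            dg_src = dg[src] if src in dg else 0.0
            k_fwd = TS_PREFACTOR * math.exp((dg_src - ts_dg) / rt)
            p_src = pops.get(src, p_f)
            p_dst = pops.get(dst, p_f)
            k_rev = k_fwd * p_src / p_dst
            a, b = sorted((src, dst))
            kinetics[f"kex_{a}{b}"] = k_fwd + k_rev
        network = make_ff_model("four_state", kinetics, temperature=T)
        points.append(UreaPoint(urea=urea, network=network))
    return points


def make_spin_set(n: int, nucleus: str = "15N",
                  minor_states: tuple[str, ...] = ("I1", "I2", "U"),
                  dw_range: tuple[float, float] = (-6.0, 6.0),
                  seed: int = 0, carrier: float | None = None,
                  r1: float = 2.0, r2: float = 20.0) -> list[SpinSystem]:
    """Deterministic, seeded set of spins for synthetic profiles.

    The first spins are hand-placed "reporters": two with large, distinct
    shift differences to the I2 and U states (>= 2 ppm) so every minor dip
    is identifiable in at least one profile, and one whose I1 and U shift
    differences nearly coincide, mimicking the broad merged dip produced
    by rapid I1 <-> U exchange.  The remainder draw their shift
    differences uniformly from ``dw_range``.
    """
    if n < 1:
        raise ValueError("need at least one spin")
    if dw_range[1] <= dw_range[0]:
        raise ValueError("empty delta-omega range")
    carrier = CARRIER[nucleus] if carrier is None else carrier
    scale = 1.0 if nucleus != "1H" else 0.25  # protons disperse ~4x less

    reporters = [
        {"I2": 3.5, "U": -5.5, "I1": 2.0},
        {"I2": -2.8, "U": 4.5, "I1": -1.8},
        {"I2": 1.2, "U": -3.35, "I1": -3.0},  # dw_I1 ~ dw_U: merged dip
    ]
    rng = np.random.default_rng(seed)
    spins = []
    for i in range(n):
        if i < len(reporters):
            dw = {s: reporters[i][s] * scale for s in minor_states}
        else:
            dw = {s: float(rng.uniform(*dw_range)) * scale
                  for s in minor_states}
        omega = carrier + float(rng.uniform(-3.0, 3.0)) * scale
        spins.append(SpinSystem(spin_id=f"s{i}", nucleus=nucleus,
                                omega_major=omega, delta_omega=dw,
                                r1=r1, r2=r2))
    return spins


def generate_profiles(scn: Scenario, spins: list[SpinSystem] | None = None,
                      noise_sd: float | None = None, seed: int | None = None,
                      ) -> tuple[list[CESTProfile], dict]:
    """Forward-simulate every (spin, B1) profile, optionally with noise.

    Gaussian intensity noise of standard deviation ``noise_sd`` (as a
    fraction of the reference intensity I0) is added independently per
    point, using a seeded generator; with noise the per-point error column
    is set to the true noise SD.  Returns the profiles together with a
    ground-truth dictionary (kinetics, per-spin parameters, acquisition
    settings) suitable for serialization and recovery tests.
    """
    noise_sd = scn.noise_sd if noise_sd is None else noise_sd
    seed = scn.seed if seed is None else seed
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if spins is None:
        minors = {"two_state": ("I2",), "three_state": ("I1", "I2"),
                  "four_state": ("I1", "I2", "U")}[scn.level]
        spins = make_spin_set(scn.n_spins, nucleus=scn.nucleus,
                              minor_states=minors, seed=seed,
                              carrier=scn.carrier)
    network = scn.network()
    rng = np.random.default_rng(seed)

    profiles = []
    for spin in spins:
        for exp in scn.experiments():
            prof = simulate_profile(spin, network, exp)
            if noise_sd > 0:
                noisy = prof.intensities + rng.normal(0.0, noise_sd,
                                                      prof.intensities.size)
                prof = CESTProfile(exp, spin.spin_id, noisy,
                                   np.full(noisy.size, noise_sd))
            profiles.append(prof)

    truth = {
        "scenario": {
            "name": scn.name, "level": scn.level,
            "temperature_c": scn.temperature_c,
            "t_ex": scn.t_ex,
            "spectrometer_1h_freq_mhz": scn.spectrometer_1h_freq,
            "carrier_ppm": scn.carrier, "nucleus": scn.nucleus,
            "b1_hz": list(scn.b1_hz),
            "noise_sd": noise_sd, "seed": seed,
        },
        "kinetics": dict(scn.kinetics),
        "spins": {
            spin.spin_id: {
                "omega_major": spin.omega_major,
                "r1": spin.r1, "r2": spin.r2,
                **{f"dw_{s}": v for s, v in spin.delta_omega.items()},
            } for spin in spins
        },
    }
    return profiles, truth
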