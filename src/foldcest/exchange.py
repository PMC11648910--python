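"""N-state exchange kinetics: networks, populations, rates, rate matrices.

Exchange between a pair of states J and K is parameterized by the total
exchange rate constant ``k_ex,JK = k_JK + k_KJ`` together with the
equilibrium populations, never by the microscopic rates directly.  The
microscopic rates follow from detailed balance at equilibrium,

    k_JK = k_ex * p_K / (p_J + p_K),    k_KJ = k_ex * p_J / (p_J + p_K),

so that p_J * k_JK = p_K * k_KJ on every edge and the equilibrium
population vector is stationary under the first-order rate matrix.

Rate-matrix convention (used everywhere in the package):
``dp/dt = K @ p`` with off-diagonal ``K[i, j] = k_{j -> i}`` and diagonal
entries equal to minus the column outflow, so columns sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticNetwork",
    "microscopic_rates",
    "build_rate_matrix",
    "make_ff_model",
]

#: Folding-network topology used for the four-state FF-domain model: the
#: native state F exchanges with both intermediates, the intermediates
#: exchange with each other, and only I1 exchanges with the unfolded state.
FF_FOUR_STATE_EDGES = (("F", "I1"), ("F", "I2"), ("I1", "I2"), ("I1", "U"))


def microscopic_rates(k_ex: float, p_a: float, p_b: float,
                      labels: tuple[str, str] = ("A", "B")) -> tuple[float, float]:
    """Split a pairwise exchange rate into microscopic rates.

    Parameters
    ----------
    k_ex : float
        Total exchange rate constant k_AB + k_BA (s^-1), >= 0.
    p_a, p_b : float
        Equilibrium populations of the two states (fractions, > 0).
    labels : tuple of str, optional
        State names used in error messages.

    Returns
    -------
    (k_ab, k_ba) : tuple of float
        Microscopic rates A->B and B->A in s^-1, satisfying
        ``k_ab + k_ba == k_ex`` and detailed balance
        ``p_a * k_ab == p_b * k_ba``.
    """
    if k_ex < 0:
        raise ValueError(f"k_ex must be >= 0, got {k_ex}")
    for p, name in ((p_a, labels[0]), (p_b, labels[1])):
        if p <= 0:
            raise ValueError(f"population of state {name!r} must be > 0, got {p}")
    total = p_a + p_b
    return k_ex * p_b / total, k_ex * p_a / total


@dataclass(frozen=True)
class KineticNetwork:
    """An N-state first-order exchange network at equilibrium.

    Attributes
    ----------
    state_labels : tuple of str
        Ordered state names; the first state is the observed (major) state.
    populations : numpy.ndarray
        Fractional equilibrium occupancies, strictly positive, summing to 1.
    edges : dict
        Maps frozenset({J, K}) -> k_ex,JK in s^-1.  Pairs absent from the
        map do not exchange.
    temperature : float
        Sample temperature in Kelvin (used by the thermodynamic layer).
    """

    state_labels: tuple[str, ...]
    populations: np.ndarray
    edges: dict[frozenset, float] = field(default_factory=dict)
    temperature: float = 298.15

    def __post_init__(self):
        pops = np.asarray(self.populations, dtype=float)
        object.__setattr__(self, "populations", pops)
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        if pops.shape != (len(self.state_labels),):
            raise ValueError("one population per state required")
        for label, p in zip(self.state_labels, pops):
            if p <= 0:
                raise ValueError(f"population of state {label!r} must be > 0, got {p}")
        if abs(pops.sum() - 1.0) > 1e-12:
            raise ValueError(f"populations must sum to 1, got {pops.sum()!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        for pair, k_ex in self.edges.items():
            unknown = set(pair) - set(self.state_labels)
            if unknown:
                raise ValueError(f"edge references unknown state(s) {sorted(unknown)}")
            if len(pair) != 2:
                raise ValueError(f"edge {set(pair)} must join two distinct states")
            if k_ex < 0:
                raise ValueError(f"k_ex for edge {set(pair)} must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def index(self, label: str) -> int:
        return self.state_labels.index(label)

    def population(self, label: str) -> float:
        return float(self.populations[self.index(label)])

    def k_ex(self, a: str, b: str) -> float:
        """Total exchange rate on edge {a, b}; 0 if the pair does not exchange."""
        return float(self.edges.get(frozenset((a, b)), 0.0))

    def microscopic_rate(self, source: str, dest: str) -> float:
        """Microscopic first-order rate k_{source -> dest} in s^-1."""
        k_ex = self.k_ex(source, dest)
        if k_ex == 0.0:
            return 0.0
        k_fwd, _ = microscopic_rates(
            k_ex, self.population(source), self.population(dest),
            labels=(source, dest))
        return k_fwd


def build_rate_matrix(network: KineticNetwork) -> np.ndarray:
    """Assemble the N x N first-order rate matrix K with dp/dt = K @ p.

    Off-diagonal entry (i, j) is the microscopic rate from state j into
    state i; each diagonal entry carries minus the outflow of its column,
    so every column sums to zero and ``K @ p == 0`` at equilibrium.
    """
    n = network.n_states
    K = np.zeros((n, n))
    for pair, k_ex in network.edges.items():
        a, b = sorted(pair)
        i, j = network.index(a), network.index(b)
        k_ab, k_ba = microscopic_rates(
            k_ex, network.populations[i], network.populations[j], labels=(a, b))
        K[j, i] += k_ab  # a -> b feeds row b from column a
        K[i, j] += k_ba
        K[i, i] -= k_ab
        K[j, j] -= k_ba
    return K


_FF_LEVELS = {
    "two_state": ("F", "I2"),
    "three_state": ("F", "I1", "I2"),
    "four_state": ("F", "I1", "I2", "U"),
}

# (kinetic rate keys, minor population keys) required per model level
_FF_PARAMS = {
    "two_state": (("kex_FI2",), ("p_I2",)),
    "three_state": (("kex_FI1", "kex_FI2", "kex_I1I2"), ("p_I1", "p_I2")),
    "four_state": (("kex_FI1", "kex_FI2", "kex_I1I2", "kex_I1U"),
                   ("p_I1", "p_I2", "p_U")),
}


def make_ff_model(level: str, params: dict[str, float],
                  temperature: float = 283.15) -> KineticNetwork:
    """Build a folded/intermediate/unfolded exchange network.

    Parameters
    ----------
    level : {"two_state", "three_state", "four_state"}
        two_state: F <-> I2; three_state: F, I1, I2 fully connected via
        F-I1, F-I2, I1-I2; four_state adds U exchanging with I1 only.
    params : dict
        Exchange rates (s^-1) keyed ``kex_<A><B>`` and minor-state
        populations (fractions) keyed ``p_<X>``; the major-state population
        is the complement.
    temperature : float
        Kelvin.  Celsius inputs must be converted by the caller
        (add 273.15).
    """
    if level not in _FF_LEVELS:
        raise ValueError(f"unknown model level {level!r}; "
                         f"choose from {sorted(_FF_LEVELS)}")
    labels = _FF_LEVELS[level]
    rate_keys, pop_keys = _FF_PARAMS[level]
    missing = [k for k in rate_keys + pop_keys if k not in params]
    if missing:
        raise ValueError(f"missing parameters for {level}: {missing}")

    minors = {k[2:]: float(params[k]) for k in pop_keys}
    p_minor = sum(minors.values())
    if p_minor >= 1.0:
        raise ValueError(
            f"minor-state populations sum to {p_minor:.4g} >= 1")
    pops = np.array([1.0 - p_minor] + [minors[s] for s in labels[1:]])

    edges = {}
    for key in rate_keys:
        a, b = _split_edge_key(key, labels)
        edges[frozenset((a, b))] = float(params[key])
    return KineticNetwork(labels, pops, edges, temperature=temperature)


def _split_edge_key(key: str, labels: tuple[str, ...]) -> tuple[str, str]:
    """Parse 'kex_FI2' -> ('F', 'I2') against the known state labels."""
    body = key[len("kex_"):]
    for a in labels:
        if body.startswith(a) and body[len(a):] in labels:
            return a, body[len(a):]
    raise ValueError(f"cannot parse edge key {key!r} for states {labels}")
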