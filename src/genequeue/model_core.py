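"""Model parameterization, steady-state means, Jacobian and timescales.

The reaction scheme describes a single gene copy cycling through ``G``
sequential promoter states (activation, RNAP binding, open-complex
formation, promoter-proximal pausing), producing nascent mRNA that matures
through ``S`` nuclear stages (processing at rate ``delta``, export at rate
``delta1``), ``R`` cytoplasmic stages (each at rate ``lam``, the last one
being degradation), translation from the first cytoplasmic stage at rate
``lam1`` and protein decay at rate ``lam2``.  Elongation plus termination
is a deterministic delay ``T_elong``; because it merely shifts arrival
times it leaves every steady-state quantity of interest unchanged.

All rates are in 1/min, the delay in min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "SteadyStateMeans",
    "TimescaleReport",
    "esp",
    "esp_enumerate",
    "steady_state_means",
    "rate_equations_rhs",
    "full_jacobian",
    "timescales",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Full parameter set of the multi-stage gene expression scheme.

    Parameters
    ----------
    G, S, R
        Number of promoter states, nuclear mRNA stages and cytoplasmic
        mRNA stages (all >= 1).
    k_on, k_off
        Gene activation / deactivation rates (1/min); ``k_off`` may be 0
        (constitutive gene).
    k
        Per-step initiation rates ``k_1 .. k_G`` (1/min), length ``G``.
    delta, delta1
        Nuclear processing rate (used for stages ``1..S-1``) and nuclear
        export rate (1/min).  For ``S = 1`` only ``delta1`` matters.
    lam, lam1, lam2
        Cytoplasmic stage rate, translation rate and protein decay rate
        (1/min).
    T_elong
        Deterministic elongation + termination delay (min, >= 0).
    """

    G: int
    S: int
    R: int
    k_on: float
    k_off: float
    k: tuple[float, ...]
    delta: float
    delta1: float
    lam: float = 1.0
    lam1: float = 1.0
    lam2: float = 1.0
    T_elong: float = 0.0

    def __post_init__(self) -> None:
        if self.G < 1 or self.S < 1 or self.R < 1:
            raise ValueError("stage counts G, S, R must be >= 1")
        object.__setattr__(self, "k", tuple(float(x) for x in self.k))
        if len(self.k) != self.G:
            raise ValueError(f"k must have length G={self.G}, got {len(self.k)}")
        strict = {"k_on": self.k_on, "delta": self.delta, "delta1": self.delta1,
                  "lam": self.lam, "lam1": self.lam1, "lam2": self.lam2}
        strict.update({f"k[{i + 1}]": ki for i, ki in enumerate(self.k)})
        for name, value in strict.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"rate {name} must be strictly positive, got {value}")
        if not np.isfinite(self.k_off) or self.k_off < 0:
            raise ValueError(f"k_off must be >= 0, got {self.k_off}")
        if not np.isfinite(self.T_elong) or self.T_elong < 0:
            raise ValueError(f"T_elong must be >= 0, got {self.T_elong}")

    @property
    def n_state(self) -> int:
        """Dimension of the reduced mean-field state (U_G eliminated)."""
        return self.G + self.S + self.R + 1

    def with_(self, **changes) -> "GeneModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class SteadyStateMeans:
    """Steady-state occupancies and mean molecule numbers.

    ``U`` has length ``G + 1`` (gene-state probabilities, summing to 1),
    ``MN`` length ``S``, ``MC`` length ``R``; ``P`` is the protein mean.
    """

    U: np.ndarray
    MN: np.ndarray
    MC: np.ndarray
    P: float

    def as_state(self) -> np.ndarray:
        """Reduced state vector (U0..U_{G-1}, MN, MC, P) for the rate ODEs."""
        return np.concatenate([self.U[:-1], self.MN, self.MC, [self.P]])


@dataclass(frozen=True)
class TimescaleReport:
    """Species-block timescales (min) and their separation parameters."""

    tau_G: np.ndarray
    tau_N: np.ndarray
    tau_C: np.ndarray
    tau_P: np.ndarray

    def tau(self, block: str) -> np.ndarray:
        return {"G": self.tau_G, "N": self.tau_N,
                "C": self.tau_C, "P": self.tau_P}[block]

    def Lambda(self, i: str, j: str) -> float:
        """Separation parameter max(tau_i)/min(tau_j); << 1 means i is fast."""
        return float(np.max(self.tau(i)) / np.min(self.tau(j)))


# ---------------------------------------------------------------------------
# Elementary symmetric polynomials
# ---------------------------------------------------------------------------

def esp(g: int, values: Sequence[float]) -> float:
    """Elementary symmetric polynomial e_g of the given values.

    Total function: returns 1 for ``g == 0`` and 0 for ``g < 0`` or
    ``g > len(values)``.  Computed by the stable Newton recursion
    ``e_g(x_1..x_n) = e_g(x_1..x_{n-1}) + x_n e_{g-1}(x_1..x_{n-1})``
    in O(n*g) operations.
    """
    values = list(values)
    n = len(values)
    if g < 0 or g > n:
        return 0.0
    if g == 0:
        return 1.0
    # e[j] holds e_j of the prefix processed so far, j = 0..g
    e = np.zeros(g + 1)
    e[0] = 1.0
    for x in values:
        hi = min(g, n)  # upper bound irrelevant; update downwards
        for j in range(hi, 0, -1):
            e[j] += x * e[j - 1]
    return float(e[g])


def esp_enumerate(g: int, values: Sequence[float]) -> float:
    """Brute-force e_g by subset enumeration (test oracle, n <= ~20)."""
    from itertools import combinations

    values = list(values)
    if g < 0 or g > len(values):
        return 0.0
    return float(sum(np.prod(c) for c in combinations(values, g)) if g else 1.0)


# ---------------------------------------------------------------------------
# Steady-state means
# ---------------------------------------------------------------------------

def _denominator(m: GeneModel) -> float:
    """k_on e_{G-1}(k_1..k_G) + k_off e_{G-1}(k_2..k_G)."""
    return m.k_on * esp(m.G - 1, m.k) + m.k_off * esp(m.G - 1, m.k[1:])


def steady_state_means(m: GeneModel) -> SteadyStateMeans:
    """Closed-form steady-state means of the rate equations.

    The gene-state occupancies are U_0 = k_off e_{G-1}(k_2..k_G)/den and
    U_g = k_on (prod_i k_i)/k_g / den; every nuclear stage below the last
    carries flux/delta molecules, the last flux/delta1, every cytoplasmic
    stage flux/lam, and the protein mean is lam1/lam2 times the mean of
    the first cytoplasmic stage, where flux = k_on prod_i k_i / den is the
    mean transcription rate and den the normalizing factor above.
    """
    den = _denominator(m)
    prod_k = float(np.prod(m.k))  # e_{G+1}(k_on, k_1..k_G) / k_on
    flux = m.k_on * prod_k / den  # = e_{G+1}(k_on,k_1..k_G)/den, 1/min

    U = np.empty(m.G + 1)
    U[0] = m.k_off * esp(m.G - 1, m.k[1:]) / den
    for g in range(1, m.G + 1):
        U[g] = m.k_on * prod_k / m.k[g - 1] / den

    MN = np.full(m.S, flux / m.delta)
    MN[-1] = flux / m.delta1
    MC = np.full(m.R, flux / m.lam)
    P = m.lam1 * flux / (m.lam2 * m.lam)
    return SteadyStateMeans(U=U, MN=MN, MC=MC, P=float(P))


def mean_transcription_rate(m: GeneModel) -> float:
    """Mean rate of nascent mRNA production, k_G <U_G> (1/min)."""
    return m.k_on * float(np.prod(m.k)) / _denominator(m)


def on_fraction(m: GeneModel) -> float:
    """Nominal on-state duty cycle k_on/(k_on + k_off).

    This is the on-fraction of the activation/deactivation switch viewed
    in isolation; the exact occupancy of the states U_1..U_G additionally
    reflects the time spent traversing the initiation steps and is given
    by 1 - U_0 of :func:`steady_state_means`.
    """
    return m.k_on / (m.k_on + m.k_off)


# ---------------------------------------------------------------------------
# Rate equations and Jacobian
# ---------------------------------------------------------------------------

def rate_equations_rhs(m: GeneModel, state: np.ndarray) -> np.ndarray:
    """Right-hand side of the deterministic rate equations.

    ``state`` is ordered (U_0..U_{G-1}, MN_1..MN_S, MC_1..MC_R, P); the
    last gene state is eliminated through U_G = 1 - sum(U_g).  Nascent
    mRNA is not tracked: the elongation delay does not affect the
    steady-state statistics of the mature species.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (m.n_state,):
        raise ValueError(f"state must have shape ({m.n_state},), got {state.shape}")
    G, S, R = m.G, m.S, m.R
    U = state[:G]
    MN = state[G:G + S]
    MC = state[G + S:G + S + R]
    P = state[-1]
    UG = 1.0 - U.sum()
    k = m.k

    dU = np.empty(G)
    if G == 1:
        # U1 is the eliminated state; U0 exchanges with it directly
        dU[0] = m.k_off * UG - m.k_on * U[0]
    else:
        dU[0] = m.k_off * U[1] - m.k_on * U[0]
        dU[1] = m.k_on * U[0] + k[G - 1] * UG - (m.k_off + k[0]) * U[1]
        for g in range(2, G):
            dU[g] = k[g - 2] * U[g - 1] - k[g - 1] * U[g]

    dMN = np.empty(S)
    influx = k[G - 1] * UG
    if S == 1:
        dMN[0] = influx - m.delta1 * MN[0]
    else:
        dMN[0] = influx - m.delta * MN[0]
        for s in range(1, S - 1):
            dMN[s] = m.delta * MN[s - 1] - m.delta * MN[s]
        dMN[S - 1] = m.delta * MN[S - 2] - m.delta1 * MN[S - 1]

    dMC = np.empty(R)
    dMC[0] = m.delta1 * MN[S - 1] - m.lam * MC[0]
    for r in range(1, R):
        dMC[r] = m.lam * MC[r - 1] - m.lam * MC[r]

    dP = m.lam1 * MC[0] - m.lam2 * P
    return np.concatenate([dU, dMN, dMC, [dP]])


def full_jacobian(m: GeneModel) -> np.ndarray:
    """Constant Jacobian of :func:`rate_equations_rhs` (system is linear).

    Assembled column-by-column from the RHS at unit perturbations; the
    affine offset (from the eliminated U_G) drops out of differences.
    """
    n = m.n_state
    x0 = np.zeros(n)
    f0 = rate_equations_rhs(m, x0)
    J = np.empty((n, n))
    for j in range(n):
        x = np.zeros(n)
        x[j] = 1.0
        J[:, j] = rate_equations_rhs(m, x) - f0
    return J


def gene_jacobian(m: GeneModel) -> np.ndarray:
    """Gene-block sub-Jacobian (top-left G x G block)."""
    return full_jacobian(m)[:m.G, :m.G]


def timescales(m: GeneModel) -> TimescaleReport:
    """Species-block timescales from the block-triangular Jacobian.

    The gene block feeds nuclear mRNA, which feeds cytoplasmic mRNA,
    which feeds protein, so the Jacobian is block lower-triangular and
    the block eigenvalues are exact eigenvalues of the full system:
    the nuclear chain contributes -delta (S-1 times) and -delta1, the
    cytoplasmic chain -lam (R times), the protein row -lam2.
    """
    eig_G = np.linalg.eigvals(gene_jacobian(m))
    tau_G = 1.0 / np.abs(eig_G.real)
    tau_N = np.array([1.0 / m.delta] * (m.S - 1) + [1.0 / m.delta1])
    tau_C = np.full(m.R, 1.0 / m.lam)
    tau_P = np.array([1.0 / m.lam2])
    return TimescaleReport(tau_G=tau_G, tau_N=tau_N, tau_C=tau_C, tau_P=tau_P)
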