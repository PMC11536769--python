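"""Linear-noise analysis: exact Lyapunov oracle and slow-scale closed forms.

Because every propensity in the reaction scheme is linear in the molecule
numbers, the linear noise approximation is exact for the first two
moments: the stationary covariance solves J C + C J^T + D = 0 with J the
rate-equation Jacobian and D the diffusion matrix assembled from the
steady-state propensities.  :func:`lna_full_covariance` solves that
system numerically on the complete network and serves as the oracle.

When the cytoplasmic mRNA (or protein) species are much slower than
everything upstream, the slow-scale LNA yields closed-form Fano factors
expressed through elementary symmetric polynomials of the initiation
rates.  These closed forms predict the sub/super-Poissonian threshold in
the deactivation rate, the three qualitative behaviours of the Fano
factor as a function of k_off, the monotonicity in the number of
processing stages, and parameter-free lower bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .model_core import (GeneModel, esp, full_jacobian, steady_state_means,
                         mean_transcription_rate)

__all__ = [
    "CovarianceResult",
    "CaseLabel",
    "lna_full_covariance",
    "lna_block",
    "sslna_ff_cyto",
    "sslna_ff_nuclear",
    "sslna_cov_cyto",
    "sslna_cv2_cyto",
    "sslna_ff_protein",
    "koff_threshold",
    "koff_threshold_equal_rates",
    "case_thresholds",
    "classify_cases",
    "min_ff_cyto",
    "min_ff_protein",
    "ff_vs_R_monotonicity",
    "double_factorial_ratio",
]


@dataclass(frozen=True)
class CovarianceResult:
    """Stationary covariance of a species block with summary statistics."""

    cov: np.ndarray
    means: np.ndarray
    fano_total: float
    cv2_total: float
    species: tuple[str, ...] = ()

    @classmethod
    def from_block(cls, cov: np.ndarray, means: np.ndarray,
                   species: tuple[str, ...] = ()) -> "CovarianceResult":
        total_mean = float(np.sum(means))
        total_var = float(np.sum(cov))
        return cls(cov=cov, means=means,
                   fano_total=total_var / total_mean,
                   cv2_total=total_var / total_mean**2,
                   species=species)


@dataclass(frozen=True)
class CaseLabel:
    """Qualitative behaviour of FF vs k_off and the associated thresholds.

    case_id 1: FF dips below its asymptote then rises back towards 1 from
    below (minimum at koff_crit); 2: monotonic increase towards 1 from
    below; 3: rises above 1, peaks at koff_crit, then decays to 1 from
    above.
    """

    case_id: int
    k1_star: float
    kon1_star: float
    kon2_star: float
    koff_crit: float | None


# ---------------------------------------------------------------------------
# Full-network Lyapunov oracle
# ---------------------------------------------------------------------------

def _reactions(m: GeneModel):
    """(stoichiometry, steady-state propensity) pairs in reduced coordinates.

    Reduced state order: U_0..U_{G-1}, MN_1..MN_S, MC_1..MC_R, P, with
    U_G eliminated by the gene-state conservation law.
    """
    G, S, R = m.G, m.S, m.R
    n = m.n_state
    ss = steady_state_means(m)
    U, MN, MC, P = ss.U, ss.MN, ss.MC, ss.P
    iU = lambda g: g
    iN = lambda s: G + s
    iC = lambda r: G + S + r
    iP = n - 1
    out = []

    if G == 1:
        # U_1 is the eliminated state; its occupancy is U[1] = 1 - U[0]
        nu = np.zeros(n); nu[iU(0)] = -1
        out.append((nu, m.k_on * U[0]))
        nu = np.zeros(n); nu[iU(0)] = +1
        out.append((nu, m.k_off * U[1]))
        nu = np.zeros(n); nu[iN(0)] = +1
        out.append((nu, m.k[0] * U[1]))
    else:
        nu = np.zeros(n); nu[iU(0)] = -1; nu[iU(1)] = +1
        out.append((nu, m.k_on * U[0]))
        nu = np.zeros(n); nu[iU(1)] = -1; nu[iU(0)] = +1
        out.append((nu, m.k_off * U[1]))
        for g in range(1, G):  # U_g -> U_{g+1}, rate k_g
            nu = np.zeros(n); nu[iU(g)] = -1
            if g + 1 <= G - 1:
                nu[iU(g + 1)] = +1
            out.append((nu, m.k[g - 1] * U[g]))
        # U_G -> U_1 + MN_1 (delay collapsed)
        nu = np.zeros(n); nu[iU(1)] = +1; nu[iN(0)] = +1
        out.append((nu, m.k[G - 1] * U[G]))
    if S == 1:
        nu = np.zeros(n); nu[iN(0)] = -1; nu[iC(0)] = +1
        out.append((nu, m.delta1 * MN[0]))
    else:
        for s in range(S - 1):
            nu = np.zeros(n); nu[iN(s)] = -1; nu[iN(s + 1)] = +1
            out.append((nu, m.delta * MN[s]))
        nu = np.zeros(n); nu[iN(S - 1)] = -1; nu[iC(0)] = +1
        out.append((nu, m.delta1 * MN[S - 1]))
    for r in range(R - 1):
        nu = np.zeros(n); nu[iC(r)] = -1; nu[iC(r + 1)] = +1
        out.append((nu, m.lam * MC[r]))
    nu = np.zeros(n); nu[iC(R - 1)] = -1
    out.append((nu, m.lam * MC[R - 1]))
    nu = np.zeros(n); nu[iP] = +1
    out.append((nu, m.lam1 * MC[0]))
    nu = np.zeros(n); nu[iP] = -1
    out.append((nu, m.lam2 * P))
    return out


def diffusion_matrix(m: GeneModel) -> np.ndarray:
    """D = sum_j nu_j nu_j^T a_j(x_ss) over all reactions."""
    n = m.n_state
    D = np.zeros((n, n))
    for nu, a in _reactions(m):
        D += a * np.outer(nu, nu)
    return D


def lna_full_covariance(m: GeneModel) -> CovarianceResult:
    """Exact stationary covariance of the full network (delay collapsed).

    Solves the matrix Lyapunov equation J C + C J^T + D = 0; for this
    first-order network the result coincides with the exact moments of
    the chemical master equation.
    """
    J = full_jacobian(m)
    D = diffusion_matrix(m)
    C = linalg.solve_continuous_lyapunov(J, -D)
    C = 0.5 * (C + C.T)
    resid = np.linalg.norm(J @ C + C @ J.T + D)
    if resid > 1e-9 * max(np.linalg.norm(D), 1.0):
        raise RuntimeError(f"Lyapunov solve failed: residual {resid:.2e}")
    ss = steady_state_means(m)
    means = ss.as_state()
    names = tuple([f"U{g}" for g in range(m.G)]
                  + [f"MN{s + 1}" for s in range(m.S)]
                  + [f"MC{r + 1}" for r in range(m.R)] + ["P"])
    return CovarianceResult.from_block(C, means, names)


def lna_block(m: GeneModel, block: str) -> CovarianceResult:
    """Covariance of one species block (nuclear / cytoplasmic / protein)."""
    full = lna_full_covariance(m)
    G, S, R = m.G, m.S, m.R
    sl = {"nuclear": slice(G, G + S),
          "cytoplasmic": slice(G + S, G + S + R),
          "protein": slice(G + S + R, G + S + R + 1)}[block]
    return CovarianceResult.from_block(full.cov[sl, sl], full.means[sl],
                                       full.species[sl])


# ---------------------------------------------------------------------------
# ssLNA closed forms (cytoplasmic mRNA)
# ---------------------------------------------------------------------------

def double_factorial_ratio(R: int) -> float:
    """(2R-1)!!/(2R)!! = prod_{i=1..R} (2i-1)/(2i); decreasing in R."""
    if R < 0:
        raise ValueError("R must be >= 0")
    if R <= 150:
        out = 1.0
        for i in range(1, R + 1):
            out *= (2 * i - 1) / (2 * i)
        return out
    acc = 0.0
    for i in range(1, R + 1):
        acc += math.log(2 * i - 1) - math.log(2 * i)
    return math.exp(acc)


def _esp_parts(m: GeneModel):
    k = m.k
    A = esp(m.G - 1, k[1:])        # e_{G-1}(k_2..k_G)
    B = esp(m.G - 2, k[1:])        # e_{G-2}(k_2..k_G)
    C = esp(m.G - 2, k)            # e_{G-2}(k_1..k_G)
    eG = esp(m.G, k)               # prod k_i
    den = m.k_off * A + m.k_on * esp(m.G - 1, k)
    return A, B, C, eG, den


def _ff_numerator(m: GeneModel) -> float:
    """k_off(e_{G-1}(k_2..) - k_on e_{G-2}(k_2..)) - k_on^2 e_{G-2}(k_1..).

    The sign of this quantity is the sign of FF - 1 for both cytoplasmic
    mRNA and (shifted) every off-diagonal covariance.
    """
    A, B, C, _, _ = _esp_parts(m)
    return m.k_off * (A - m.k_on * B) - m.k_on**2 * C


def sslna_ff_cyto(m: GeneModel) -> float:
    """Slow-scale Fano factor of total cytoplasmic mRNA.

    FF = 1 + 2 e_G (1 - (2R-1)!!/(2R)!!) nu / den^2 with nu the threshold
    numerator and den = k_off e_{G-1}(k_2..k_G) + k_on e_{G-1}(k_1..k_G).
    Accurate when Lambda_{G,C} and Lambda_{N,C} are << 1; independent of
    the nuclear rates delta, delta1 and of lam.
    """
    _, _, _, eG, den = _esp_parts(m)
    nu = _ff_numerator(m)
    return 1.0 + 2.0 * eG * (1.0 - double_factorial_ratio(m.R)) * nu / den**2


def sslna_ff_nuclear(m: GeneModel) -> float:
    """Slow-scale Fano factor of total nuclear mRNA (requires delta = delta1).

    Identical to the cytoplasmic expression with R replaced by S: the
    nuclear cascade then plays the role of the processing chain.
    """
    _, _, _, eG, den = _esp_parts(m)
    nu = _ff_numerator(m)
    return 1.0 + 2.0 * eG * (1.0 - double_factorial_ratio(m.S)) * nu / den**2


def _reduced_cyto_matrices(m: GeneModel):
    """Reduced Jacobian and diffusion matrices of the cytoplasmic block."""
    R = m.R
    Js = -m.lam * np.eye(R)
    for i in range(1, R):
        Js[i, i - 1] = m.lam
    mc = mean_transcription_rate(m) / m.lam  # common stage mean
    Ds = np.zeros((R, R))
    A, _, _, _, den = _esp_parts(m)
    k = m.k
    k_sq = tuple(ki**2 for ki in k)
    eGp1 = m.k_on * esp(m.G, k)  # e_{G+1}(k_on, k_1..k_G)
    extra = eGp1 * (m.k_on**2 * esp(m.G - 1, k_sq)
                    + esp(m.G - 1, k_sq[1:]) * (m.k_off**2
                                                + 2 * m.k_off * m.k_on
                                                + 2 * m.k_off * k[0])) / den**3
    Ds[0, 0] = m.lam * mc + extra
    for i in range(1, R):
        Ds[i, i] = m.lam * 2 * mc
        Ds[i, i - 1] = Ds[i - 1, i] = -m.lam * mc
    return Js, Ds


def sslna_cov_cyto(m: GeneModel) -> CovarianceResult:
    """Slow-scale covariance matrix of the cytoplasmic mRNA stages.

    Solves the reduced R x R Lyapunov equation Js C + C Js^T + Ds = 0
    exactly; all off-diagonal entries share the sign of FF - 1, and the
    block total reproduces :func:`sslna_ff_cyto`.
    """
    Js, Ds = _reduced_cyto_matrices(m)
    C = linalg.solve_continuous_lyapunov(Js, -Ds)
    C = 0.5 * (C + C.T)
    mc = mean_transcription_rate(m) / m.lam
    means = np.full(m.R, mc)
    return CovarianceResult.from_block(C, means,
                                       tuple(f"MC{r+1}" for r in range(m.R)))


def sslna_cv2_cyto(m: GeneModel) -> float:
    """Slow-scale CV^2 of total cytoplasmic mRNA: FF divided by the mean."""
    total_mean = m.R * mean_transcription_rate(m) / m.lam
    return sslna_ff_cyto(m) / total_mean


# ---------------------------------------------------------------------------
# Thresholds, case classification, bounds
# ---------------------------------------------------------------------------

def koff_threshold(m: GeneModel) -> float:
    """Deactivation rate at which cytoplasmic noise crosses Poisson.

    Returns k_off* = k_on^2 e_{G-2}(k_1..k_G) /
    (e_{G-1}(k_2..k_G) - k_on e_{G-2}(k_2..k_G)) when the denominator is
    positive, and inf when the gene is always sub-Poissonian (activation
    fast enough that no k_off can push the noise above Poisson).
    """
    A, B, C, _, _ = _esp_parts(m)
    gap = A - m.k_on * B
    if gap <= 0:
        return math.inf
    return m.k_on**2 * C / gap


def koff_threshold_equal_rates(G: int, k: float, k_on: float) -> float:
    """Equal-initiation-rate shortcut: G(G-1) k_on^2 / (2 (k - k_on (G-1)))."""
    gap = k - k_on * (G - 1)
    if gap <= 0:
        return math.inf
    return 0.5 * G * (G - 1) * k_on**2 / gap


def _ff_of_koff(m: GeneModel, koff: float) -> float:
    return sslna_ff_cyto(m.with_(k_off=koff))


def case_thresholds(k: tuple[float, ...]) -> tuple[float, float, float]:
    """(k1*, k_on,1*, k_on,2*) thresholds of the case classification.

    k1*   = e_{G-1}(k_2..) e_{G-2}(k_2..) / e_{G-2}(k_2^2..),
    kon1* = e_{G-1}(k_2..) / e_{G-2}(k_2..),
    kon2* = e_{G-1}(k_2..) e_{G-1}(k_1..) /
            (k_1 e_{G-2}(k_2^2..) - e_{G-1}(k_2..) e_{G-2}(k_2..)).
    """
    G = len(k)
    k_sq = tuple(ki**2 for ki in k)
    A = esp(G - 1, k[1:])
    B = esp(G - 2, k[1:])
    Bsq = esp(G - 2, k_sq[1:])
    k1_star = A * B / Bsq if Bsq > 0 else math.inf
    kon1_star = A / B if B > 0 else math.inf
    gap = k[0] * Bsq - A * B
    kon2_star = A * esp(G - 1, k) / gap if gap > 0 else math.inf
    return float(k1_star), float(kon1_star), float(kon2_star)


def classify_cases(m: GeneModel) -> CaseLabel:
    """Classify the qualitative dependence of the cytoplasmic FF on k_off.

    The thresholds are ratios of elementary symmetric polynomials of the
    downstream initiation rates; the interior extremum koff_crit (cases 1
    and 3) is located by bounded scalar optimization on a log axis.
    """
    k = m.k
    k1_star, kon1_star, kon2_star = case_thresholds(k)
    if m.k_on < kon1_star:
        case_id = 3
    elif k[0] > k1_star and m.k_on > kon2_star:
        case_id = 1
    else:
        case_id = 2
    koff_crit = None
    if case_id in (1, 3):
        sign = 1.0 if case_id == 1 else -1.0
        res = optimize.minimize_scalar(
            lambda lx: sign * _ff_of_koff(m, 10.0**lx),
            bounds=(-6.0, 4.0), method="bounded",
            options={"xatol": 1e-8})
        koff_crit = float(10.0**res.x)
    return CaseLabel(case_id=case_id, k1_star=float(k1_star),
                     kon1_star=float(kon1_star), kon2_star=float(kon2_star),
                     koff_crit=koff_crit)


def min_ff_cyto(G: int, R: int) -> float:
    """Global lower bound of the cytoplasmic Fano factor.

    1/G + (1 - 1/G) (2R-1)!!/(2R)!!, attained for a constitutive gene
    with equal initiation rates; always > 1/G.
    """
    if G < 1 or R < 1:
        raise ValueError("G, R must be >= 1")
    return 1.0 / G + (1.0 - 1.0 / G) * double_factorial_ratio(R)


def ff_vs_R_monotonicity(m: GeneModel, R_range) -> str:
    """Trend of the cytoplasmic FF across processing-stage counts.

    Returns 'increasing', 'decreasing' or 'constant'; the trend is set by
    the sign of FF - 1 (super-Poissonian noise grows with R, sub-
    Poissonian noise shrinks, and exactly at threshold FF = 1 for all R).
    """
    R_range = list(R_range)
    if len(R_range) < 3:
        raise ValueError("need at least 3 R values")
    ffs = [sslna_ff_cyto(m.with_(R=int(R))) for R in R_range]
    diffs = np.diff(ffs)
    if np.all(np.abs(diffs) < 1e-12):
        label = "constant"
    elif np.all(diffs > 0):
        label = "increasing"
    elif np.all(diffs < 0):
        label = "decreasing"
    else:
        raise RuntimeError("non-monotonic FF(R); should not happen")
    nu = _ff_numerator(m)
    expected = "increasing" if nu > 0 else ("decreasing" if nu < 0 else "constant")
    if label != expected:
        raise RuntimeError(f"trend {label} inconsistent with sign(FF-1) {expected}")
    return label


# ---------------------------------------------------------------------------
# Protein noise
# ---------------------------------------------------------------------------

def sslna_ff_protein(m: GeneModel) -> float:
    """Slow-scale Fano factor of protein number fluctuations.

    FF = 1 + lam1/(2 lam) + lam1/(2 lam) * [e_{G-1}(k_2^2..k_G^2)
    (k_off^2 + 2 k_off (k_on + k_1)) + k_on^2 e_{G-1}(k_1^2..k_G^2)]
    / den^2.  Always > 1 and independent of S and R.
    """
    k = m.k
    k_sq = tuple(ki**2 for ki in k)
    _, _, _, _, den = _esp_parts(m)
    bracket = (esp(m.G - 1, k_sq[1:]) * (m.k_off**2 + 2 * m.k_off * (m.k_on + k[0]))
               + m.k_on**2 * esp(m.G - 1, k_sq))
    r = m.lam1 / (2.0 * m.lam)
    return 1.0 + r + r * bracket / den**2


def min_ff_protein(G: int, lam: float, lam1: float) -> float:
    """Lower bound of the protein Fano factor: 1 + lam1/(2 lam) + lam1/(2 lam G).

    Attained for a constitutive gene with equal initiation rates; tends
    to 1 + lam1/(2 lam) as the number of gene states grows.
    """
    if G < 1 or lam <= 0 or lam1 <= 0:
        raise ValueError("require G >= 1 and positive rates")
    return 1.0 + lam1 / (2.0 * lam) + lam1 / (2.0 * lam * G)
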