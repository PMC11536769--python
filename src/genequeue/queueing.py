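"""G/G/infinity queueing engine for nuclear and cytoplasmic mRNA statistics.

Transcription maps to a renewal arrival process (the promoter cycles
through its G states and emits one nascent mRNA per cycle), nuclear
processing + export to a service time, and the number of busy servers to
the number of mRNA molecules in the compartment.  The engine builds the
rational Laplace transform of the interarrival density, inverts the
renewal function by partial fractions, and evaluates the first two
binomial moments of the stationary queue length, from which the Fano
factor follows as FF = 1 + 2 B2*/B1* - B1*.

In the limit of many processing stages the service time becomes
deterministic and the stationary count distribution has an explicit
Erlang-arrival/deterministic-service form, implemented here together with
its closed-form Fano factor and coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import integrate, linalg, stats

from .model_core import GeneModel
from .simulator import CountDistribution

__all__ = [
    "InterarrivalLaplace",
    "RenewalModel",
    "ServiceTime",
    "interarrival_laplace",
    "first_passage_pdf",
    "renewal_model",
    "service_cdf",
    "phi_helper",
    "b1_of_t",
    "binomial_moments",
    "fano_nuclear",
    "fano_total_mrna",
    "delay_distribution",
    "delay_fano",
    "delay_cv",
]

# absolute tolerance for the semi-infinite binomial-moment quadratures
QUAD_ABS_TOL = 1e-10
# survival threshold at which the B2* integrand is truncated
SURVIVAL_CUTOFF = 1e-12


# ---------------------------------------------------------------------------
# Interarrival time distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterarrivalLaplace:
    """Rational Laplace transform phi(s) of the interarrival density.

    ``num``/``den`` are polynomial coefficients (highest degree first,
    ``np.polyval`` convention); ``alpha`` is the mean interarrival time,
    ``alpha2`` the second moment, ``cv2`` the squared coefficient of
    variation of the interarrival time.
    """

    num: np.ndarray
    den: np.ndarray
    alpha: float
    alpha2: float
    cv2: float

    def __call__(self, s):
        return np.polyval(self.num, s) / np.polyval(self.den, s)


def interarrival_laplace(m: GeneModel) -> InterarrivalLaplace:
    """Exact rational phi(s) for the promoter cycle of ``m``.

    phi(s) = k1 (s + k_on) / (s^2 + s (k1 + k_on + k_off) + k1 k_on)
             * prod_{i>=2} k_i / (s + k_i).

    For a constitutive gene (k_off = 0) the activation factor cancels and
    phi reduces to prod_i k_i / (s + k_i), which is used directly to keep
    numerator and denominator coprime.
    """
    k = np.asarray(m.k, dtype=float)
    if m.k_off == 0.0:
        num = np.array([float(np.prod(k))])
        den = np.array([1.0])
        for ki in k:
            den = np.polymul(den, [1.0, ki])
    else:
        num = np.array([m.k[0], m.k[0] * m.k_on]) * float(np.prod(k[1:]))
        den = np.array([1.0, m.k[0] + m.k_on + m.k_off, m.k[0] * m.k_on])
        for ki in k[1:]:
            den = np.polymul(den, [1.0, ki])

    # mean interarrival time: alpha = (k_on + k_off)/(k_on k1) + sum_{i>=2} 1/k_i
    alpha = (m.k_on + m.k_off) / (m.k_on * m.k[0]) + sum(1.0 / ki for ki in m.k[1:])
    # second moment from the Taylor expansion of phi at s = 0
    n_lo = np.concatenate([num[::-1], [0.0, 0.0]])
    d_lo = np.concatenate([den[::-1], [0.0, 0.0]])
    n0, n1, n2 = n_lo[0], n_lo[1], n_lo[2]
    d0, d1, d2 = d_lo[0], d_lo[1], d_lo[2]
    c0 = n0 / d0  # = 1 by normalization
    c1 = (n1 - c0 * d1) / d0
    c2 = (n2 - c0 * d2 - c1 * d1) / d0
    alpha2 = 2.0 * c2
    cv2 = (alpha2 - alpha**2) / alpha**2
    return InterarrivalLaplace(num=num, den=den, alpha=float(alpha),
                               alpha2=float(alpha2), cv2=float(cv2))


def first_passage_pdf(m: GeneModel, t) -> np.ndarray:
    """Interarrival density f(t) = k_G P_G(t) from the promoter master equation.

    Integrates the (G+1)-state master equation started from U_1 (matrix
    exponential of the constant generator); time-domain oracle for
    :func:`interarrival_laplace`.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    G = m.G
    A = np.zeros((G + 1, G + 1))
    A[0, 0] = -m.k_on
    A[0, 1] = m.k_off
    A[1, 0] = m.k_on
    A[1, 1] = -(m.k_off + m.k[0])
    # the production step U_G -> U_1 + M0N is absorbing for the first passage
    for i in range(2, G + 1):
        A[i, i - 1] += m.k[i - 2]
        A[i, i] -= m.k[i - 1]
    p0 = np.zeros(G + 1)
    p0[1] = 1.0
    out = np.array([m.k[G - 1] * (linalg.expm(A * ti) @ p0)[G] for ti in t])
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Renewal function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenewalModel:
    """Poles/residues representation of the renewal function R(x).

    R(x) = x/alpha - sum_r A_r (1 - e^{-s_r x}), with -s_r the nonzero
    zeros of the denominator of L{R}(s) = phi/(s(1-phi)) and
    A_r = p(-s_r)/q'(-s_r).  Complex poles come in conjugate pairs, so
    R(x) is real; c1 = (CV^2 - 1)/2 = -sum_r A_r.
    """

    poles: np.ndarray      # s_r, Re(s_r) > 0
    residues: np.ndarray   # A_r
    alpha: float
    c1: float

    @property
    def M(self) -> int:
        return len(self.poles)

    def R(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = x / self.alpha
        for s_r, A_r in zip(self.poles, self.residues):
            out = out - (A_r * (1.0 - np.exp(-s_r * x))).real
        return out

    def dR(self, x) -> np.ndarray:
        """Renewal density R'(x)."""
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, 1.0 / self.alpha)
        for s_r, A_r in zip(self.poles, self.residues):
            out = out - (A_r * s_r * np.exp(-s_r * x)).real
        return out


def renewal_model(phi: InterarrivalLaplace) -> RenewalModel:
    """Invert L{R}(s) = phi/(s(1 - phi)) by partial fractions.

    Factorizes q(s) = s^2 prod_r (s + s_r) by polynomial root finding
    (numpy companion-matrix roots polished by Newton iterations) and
    computes residues with the exact-derivative formula.
    """
    N, D = phi.num, phi.den
    # E(s) = D - N vanishes at s = 0 (phi(0)=1); W(s) = E(s)/s
    E = np.polysub(D, N)
    # remove the root at zero: constant coefficient must be ~ 0
    scale = np.max(np.abs(E))
    if abs(E[-1]) > 1e-9 * scale:
        raise ValueError("interarrival transform is not normalized: phi(0) != 1")
    W = E[:-1]
    W = np.trim_zeros(W, "f")
    if len(W) <= 1:
        # Poisson arrivals: R(x) = x/alpha exactly
        return RenewalModel(poles=np.empty(0, complex), residues=np.empty(0, complex),
                            alpha=phi.alpha, c1=phi.cv2 / 2.0 - 0.5)
    roots = np.roots(W)
    dW = np.polyder(W)
    for _ in range(3):  # Newton polish
        vals = np.polyval(W, roots)
        dvals = np.polyval(dW, roots)
        roots = roots - vals / dvals
    poles = -roots  # s_r
    if np.any(poles.real <= 0):
        raise ValueError("unstable renewal pole (Re s_r <= 0); invalid model")
    # simple-pole assumption: reject near-degenerate roots
    if len(poles) > 1:
        sc = np.max(np.abs(poles))
        for i in range(len(poles)):
            for j in range(i + 1, len(poles)):
                if abs(poles[i] - poles[j]) < 1e-8 * sc:
                    raise ValueError(
                        "repeated renewal poles detected; perturb a rate "
                        "parameter infinitesimally to separate them")
    # residues A_r = p(-s_r)/q'(-s_r) with q(s) = s^2 W(s):
    # q'(-s_r) = s_r^2 W'(-s_r) because W(-s_r) = 0
    residues = np.polyval(N, roots) / (roots**2 * np.polyval(dW, roots))
    c1 = phi.cv2 / 2.0 - 0.5
    return RenewalModel(poles=poles, residues=residues, alpha=phi.alpha, c1=c1)


# ---------------------------------------------------------------------------
# Service times
# ---------------------------------------------------------------------------

def _gammainc_lower(n: int, x) -> np.ndarray:
    """Regularized lower incomplete gamma gamma(n,x)/Gamma(n), integer n >= 0.

    Defined through the finite sum 1 - e^{-x} sum_{i<n} x^i/i!, which is
    entire in x and therefore also valid for negative arguments (needed
    when delta < delta1).  n = 0 returns 1.
    """
    x = np.asarray(x, dtype=float)
    if n == 0:
        return np.ones_like(x)
    acc = np.zeros_like(x)
    term = np.ones_like(x)
    acc += term
    for i in range(1, n):
        term = term * x / i
        acc += term
    return 1.0 - np.exp(-x) * acc


@dataclass(frozen=True)
class ServiceTime:
    """Service-time distribution of an mRNA molecule.

    kind
        ``nuclear``: Erlang(S-1, delta) convolved with Exp(delta1) —
        processing through S-1 stages followed by export.
        ``nuclear_plus_cyto``: additionally Erlang(R, lam) for the
        cytoplasmic stages (total mRNA lifetime).
        ``deterministic``: Dirac mass at T (many-stage limit).
    """

    kind: Literal["nuclear", "nuclear_plus_cyto", "deterministic"]
    S: int = 1
    delta: float = 1.0
    delta1: float = 1.0
    R: int = 0
    lam: float = 1.0
    T: float = 0.0

    @classmethod
    def nuclear(cls, m: GeneModel) -> "ServiceTime":
        return cls(kind="nuclear", S=m.S, delta=m.delta, delta1=m.delta1)

    @classmethod
    def nuclear_plus_cyto(cls, m: GeneModel) -> "ServiceTime":
        return cls(kind="nuclear_plus_cyto", S=m.S, delta=m.delta,
                   delta1=m.delta1, R=m.R, lam=m.lam)

    @classmethod
    def deterministic(cls, T: float) -> "ServiceTime":
        return cls(kind="deterministic", T=T)

    @property
    def rho(self) -> float:
        """Mean service time (min)."""
        if self.kind == "deterministic":
            return self.T
        rho = (self.S - 1) / self.delta + 1.0 / self.delta1
        if self.kind == "nuclear_plus_cyto":
            rho += self.R / self.lam
        return rho

    @property
    def stage_rates(self) -> np.ndarray:
        """Hypoexponential stage rates (empty for deterministic service)."""
        if self.kind == "deterministic":
            return np.empty(0)
        rates = [self.delta] * (self.S - 1) + [self.delta1]
        if self.kind == "nuclear_plus_cyto":
            rates += [self.lam] * self.R
        return np.asarray(rates, dtype=float)

    def _generator(self) -> np.ndarray:
        r = self.stage_rates
        Q = np.diag(-r)
        for i in range(len(r) - 1):
            Q[i, i + 1] = r[i]
        return Q

    def sf(self, t) -> np.ndarray:
        """Survival function 1 - H(t)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "deterministic":
            return np.where(t < self.T, 1.0, 0.0)
        if self.kind == "nuclear":
            return 1.0 - self._cdf_nuclear(t)
        Q = self._generator()
        flat = np.atleast_1d(t)
        out = np.array([linalg.expm(Q * ti)[0].sum() if ti > 0 else 1.0
                        for ti in flat])
        return out.reshape(t.shape)

    def cdf(self, t) -> np.ndarray:
        return 1.0 - self.sf(t)

    def _cdf_nuclear(self, t: np.ndarray) -> np.ndarray:
        d, d1, S = self.delta, self.delta1, self.S
        t = np.maximum(t, 0.0)
        if S == 1:
            return -np.expm1(-d1 * t)
        if d == d1:
            # analytic limit: the whole service is Erlang(S, delta)
            return _gammainc_lower(S, d * t)
        # the closed form loses (d/|d-d1|)^(S-1) digits to cancellation
        # when the two rates are close; switch to the phase-type matrix
        # exponential there (exact for any rates, just slower)
        if (max(d, d1) / abs(d - d1)) ** (S - 1) > 1e6:
            Q = self._generator()
            flat = np.atleast_1d(t)
            out = np.array([1.0 - linalg.expm(Q * ti)[0].sum() if ti > 0 else 0.0
                            for ti in flat])
            return out.reshape(t.shape)
        pref = (d / (d - d1)) ** (S - 1)
        return (_gammainc_lower(S - 1, d * t)
                - pref * _gammainc_lower(S - 1, (d - d1) * t) * np.exp(-d1 * t))


def service_cdf(st: ServiceTime, t) -> np.ndarray:
    """CDF of the service time at t (see :class:`ServiceTime`)."""
    return st.cdf(t)


# ---------------------------------------------------------------------------
# phi helper and B1(t)
# ---------------------------------------------------------------------------

def _phi_reg(n: int, a: float, b: complex, t: float) -> complex:
    """Regularized helper integral int_0^t gamma_reg(n, a(t-x)) e^{-bx} dx.

    Branches: b = 0 uses t*gamma_reg(n,at) - (n/a) gamma_reg(n+1,at);
    b = a uses gamma_reg(n+1, at)/a (continuity limit); otherwise
    [gamma_reg(n,at) - (a/(a-b))^n gamma_reg(n,(a-b)t) e^{-bt}]/b.
    """
    if n == 0:
        if abs(b) < 1e-300:
            return t
        return (1.0 - np.exp(-b * t)) / b
    scale = max(abs(a), 1.0)
    if abs(b) < 1e-10 * scale:
        return t * _gammainc_lower(n, a * t) - (n / a) * _gammainc_lower(n + 1, a * t)
    if abs(a - b) < 1e-10 * scale:
        return _gammainc_lower(n + 1, a * t) / a
    ab = a - b

    def _g(m: int, x: complex) -> complex:
        # gamma_reg by the same finite sum, valid for complex argument
        acc = 1.0 + 0.0j
        term = 1.0 + 0.0j
        for i in range(1, m):
            term = term * x / i
            acc += term
        return 1.0 - np.exp(-x) * acc

    return (_g(n, a * t) - (a / ab) ** n * _g(n, ab * t) * np.exp(-b * t)) / b


def phi_helper(n: int, a: float, b: float, t: float) -> float:
    """Closed form of int_0^t gamma(n, a(t-x)) e^{-bx} dx (unregularized)."""
    if n < 1:
        raise ValueError("phi_helper requires n >= 1")
    return float(np.real(math.gamma(n) * _phi_reg(n, a, b, t)))


def _service_terms(st: ServiceTime):
    """Represent H_N(u) = sum_j c_j gamma_reg(n_j, a_j u) e^{-b_j u}."""
    d, d1, S = st.delta, st.delta1, st.S
    if S == 1:
        return [(1.0, 1, d1, 0.0)]
    if abs(d - d1) < 1e-10 * d:
        return [(1.0, S, d, 0.0)]
    pref = (d / (d - d1)) ** (S - 1)
    return [(1.0, S - 1, d, 0.0), (-pref, S - 1, d - d1, d1)]


def b1_of_t(rm: RenewalModel, st: ServiceTime, t: float) -> float:
    """Time-dependent first binomial moment B1(t) of the nuclear queue.

    Evaluates the renewal-convolution B1(t) = int_0^t dR(x) (1 - H(t-x))
    in closed form through the phi helper integrals: with
    I(s, t) = int_0^t e^{-sx} H(t-x) dx,
    B1(t) = R(t) - I(0,t)/alpha + sum_r A_r s_r I(s_r, t).
    """
    if st.kind != "nuclear":
        raise ValueError("closed-form B1(t) is defined for nuclear service; "
                         "use binomial_moments for other service kinds")
    d, d1 = st.delta, st.delta1
    if st.S >= 2 and d != d1 and (max(d, d1) / abs(d - d1)) ** (st.S - 1) > 1e6:
        # near-degenerate rates: the phi-helper form cancels catastrophically
        return _b1_phase_type(rm, st, t)
    terms = _service_terms(st)

    def I(s: complex) -> complex:
        tot = 0.0 + 0.0j
        for c, n, a, b in terms:
            tot += c * np.exp(-b * t) * _phi_reg(n, a, s - b, t)
        return tot

    out = rm.R(t) - I(0.0) / rm.alpha
    for s_r, A_r in zip(rm.poles, rm.residues):
        out = out + A_r * s_r * I(s_r)
    return float(np.real(out))


def _b1_phase_type(rm: RenewalModel, st: ServiceTime, t: float) -> float:
    """B1(t) through the hypoexponential (phase-type) service representation.

    Uses int_0^t e^{-s(t-u)} (1-H(u)) du = e_1^T (Q+sI)^{-1}(e^{Qt}-e^{-st}I) 1,
    which is numerically stable for all service kinds with exponential
    stages; serves as the general pipeline for total-mRNA moments.
    """
    Q = st._generator()
    n = Q.shape[0]
    one = np.ones(n)
    E = linalg.expm(Q * t)
    a = np.zeros(n)
    a[0] = 1.0
    # J0 = int_0^t (1-H(u)) du
    J0 = a @ np.linalg.solve(Q, (E - np.eye(n))) @ one
    out = J0 / rm.alpha
    for s_r, A_r in zip(rm.poles, rm.residues):
        Ks = a @ np.linalg.solve(Q + s_r * np.eye(n),
                                 E - np.exp(-s_r * t) * np.eye(n)) @ one
        out = out - A_r * s_r * Ks
    return float(np.real(out))


# ---------------------------------------------------------------------------
# Binomial moments and Fano factors
# ---------------------------------------------------------------------------

def _truncation_time(st: ServiceTime, alpha: float) -> float:
    """Smallest multiple of max(alpha, rho) where survival < cutoff."""
    block = max(alpha, st.rho)
    t_hi = block
    while st.sf(t_hi) > SURVIVAL_CUTOFF and t_hi < 1e6 * block:
        t_hi *= 2.0
    return t_hi


def binomial_moments(m: GeneModel, st: ServiceTime, r_max: int = 2):
    """First two stationary binomial moments (B1*, B2*) of the queue.

    B1* = rho/alpha exactly; B2* = (1/alpha) int_0^inf B1(t)(1-H(t)) dt by
    adaptive quadrature, truncated where the service survival drops below
    1e-12 and split at multiples of max(alpha, rho).
    """
    phi = interarrival_laplace(m)
    rm = renewal_model(phi)
    b1_star = st.rho / phi.alpha
    if r_max < 2:
        return (b1_star,)
    t_hi = _truncation_time(st, phi.alpha)

    def integrand(t):
        if t <= 0:
            return 0.0
        return _b1_phase_type(rm, st, t) * float(st.sf(t))

    block = max(phi.alpha, st.rho)
    pts = np.arange(block, t_hi, block)[:48]
    val, err = integrate.quad(integrand, 0.0, t_hi, points=list(pts),
                              limit=200 + 10 * len(pts), epsabs=QUAD_ABS_TOL,
                              epsrel=1e-9)
    if err > max(1e-6, 1e-6 * abs(val)):
        raise RuntimeError(f"B2* quadrature did not converge: error {err:.2e}")
    b2_star = val / phi.alpha
    return b1_star, b2_star


def _fano_from_moments(b1: float, b2: float) -> float:
    return 1.0 + 2.0 * b2 / b1 - b1


def _fano_closed_s1(rm: RenewalModel, phi: InterarrivalLaplace, d1: float):
    """Both closed forms of the S=1 nuclear Fano factor (must agree)."""
    ff_res = 1.0 - float(np.real(np.sum(rm.residues * rm.poles / (rm.poles + d1)))) \
        if rm.M else 1.0
    ff_phi = 1.0 / (1.0 - float(np.real(phi(d1)))) - 1.0 / (phi.alpha * d1)
    return ff_res, ff_phi


def _fano_closed_s2(rm: RenewalModel, d: float, d1: float) -> float:
    """Closed form of the S=2 nuclear Fano factor."""
    if rm.M == 0:
        return 1.0
    s = rm.poles
    num = s * (d + d1) ** 3 + s**2 * (d**2 + 3 * d * d1 + d1**2)
    den = (d + d1) ** 2 * (d + s) * (d1 + s)
    return 1.0 - float(np.real(np.sum(rm.residues * num / den)))


def fano_nuclear(m: GeneModel, method: str = "auto") -> float:
    """Fano factor of the total nuclear mRNA count.

    Uses the exact closed forms for S = 1 and S = 2 (cross-checked
    against each other for S = 1) and the quadrature pipeline otherwise;
    ``method='quadrature'`` forces the general pipeline for any S.
    """
    phi = interarrival_laplace(m)
    rm = renewal_model(phi)
    if method == "auto" and m.S == 1:
        ff_res, ff_phi = _fano_closed_s1(rm, phi, m.delta1)
        if abs(ff_res - ff_phi) > 1e-6 * max(1.0, abs(ff_res)):
            raise RuntimeError("inconsistent S=1 closed forms: "
                               f"{ff_res} vs {ff_phi}")
        return ff_res
    if method == "auto" and m.S == 2:
        return _fano_closed_s2(rm, m.delta, m.delta1)
    st = ServiceTime.nuclear(m)
    b1, b2 = binomial_moments(m, st)
    return _fano_from_moments(b1, b2)


def fano_total_mrna(m: GeneModel) -> float:
    """Fano factor of total (nuclear + cytoplasmic) mRNA via quadrature."""
    st = ServiceTime.nuclear_plus_cyto(m)
    b1, b2 = binomial_moments(m, st)
    return _fano_from_moments(b1, b2)


# ---------------------------------------------------------------------------
# Deterministic-service (delay) limit
# ---------------------------------------------------------------------------

def _weighted_poisson_cum(n: int, x: float) -> float:
    """h(n) = sum_{j<n} (n-j) x^j e^{-x} / j! = n F(n-1) - x F(n-2).

    F is the Poisson(x) CDF; evaluated through scipy for stability at
    large x (avoids overflowing factorials).
    """
    if n <= 0:
        return 0.0
    return float(n * stats.poisson.cdf(n - 1, x) - x * stats.poisson.cdf(n - 2, x))


def delay_distribution(G: int, k: float, T: float,
                       tail: float = 1e-12) -> CountDistribution:
    """Stationary count pmf for Erlang(G,k) arrivals and deterministic service.

    Valid in the constitutive, equal-initiation-rate regime (k_off = 0,
    all k_i = k) when the compartment processing time is effectively
    fixed at T.  The pmf is a second difference of weighted Poisson
    cumulative sums; the support is truncated once the tail mass falls
    below ``tail``.
    """
    if G < 1 or k <= 0 or T <= 0:
        raise ValueError("require G >= 1, k > 0, T > 0")
    x = k * T
    pmf = []
    total = 0.0
    mean = x / G
    m_cap = int(mean + 20.0 * math.sqrt(mean + 1.0) + 60)
    h = _weighted_poisson_cum
    for mm in range(m_cap + 1):
        if mm == 0:
            p = h(G, x) / G
        else:
            p = (h(G * (mm + 1), x) - 2.0 * h(G * mm, x) + h(G * (mm - 1), x)) / G
        p = max(p, 0.0)
        pmf.append(p)
        total += p
        if total >= 1.0 - tail and mm > mean:
            break
    pmf = np.asarray(pmf)
    return CountDistribution(counts=np.arange(len(pmf)), pmf=pmf,
                             n_samples=np.inf)


def _g_delay(x: float, y: float) -> float:
    """g(x, y) = [1 - cos(x sin y) e^{-x(1-cos y)}] / [x (1 - cos y)]."""
    c = 1.0 - math.cos(y)
    return (1.0 - math.cos(x * math.sin(y)) * math.exp(-x * c)) / (x * c)


def delay_fano(G: int, x: float) -> float:
    """Closed-form Fano factor in the deterministic-service limit.

    ``x = k T`` is the dimensionless product of the per-step initiation
    rate and the processing time.  Equals 1 for G = 1 (Poisson), lies in
    (1/G, 1) for G >= 2 and decays monotonically with x.
    """
    if G < 1 or x <= 0:
        raise ValueError("require G >= 1 and x > 0")
    if G == 1:
        return 1.0
    if G % 2 == 1:
        acc = sum(_g_delay(x, 2.0 * math.pi * r / G) for r in range(1, (G - 1) // 2 + 1))
        return (1.0 + 2.0 * acc) / G
    acc = sum(_g_delay(x, 2.0 * math.pi * r / G) for r in range(1, (G - 2) // 2 + 1))
    return (1.0 + 2.0 * acc + _g_delay(x, math.pi)) / G


def delay_cv(G: int, k: float, T: float) -> float:
    """Coefficient of variation in the deterministic-service limit.

    CV = sqrt(FF / mean) with mean = k T / G; decays monotonically with T.
    """
    mean = k * T / G
    return math.sqrt(delay_fano(G, k * T) / mean)
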