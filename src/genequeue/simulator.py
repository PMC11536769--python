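"""Exact stochastic simulation of the multi-stage gene expression scheme.

The simulator produces statistically exact sample paths of the reaction
network, including (optionally) the deterministic elongation delay, and
turns a single long trajectory into a time-weighted steady-state count
distribution with batch-means Monte-Carlo errors.

Two engines are provided: a numba-compiled ergodic-averaging core used
for steady-state distributions (the delay step collapsed, which leaves
all steady-state statistics of the mature species unchanged because the
delay merely time-shifts the arrival process), and a plain-Python event
recorder that supports the explicit delay queue for validation runs.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model_core import GeneModel, steady_state_means, timescales

logger = logging.getLogger("genequeue")

__all__ = [
    "Trajectory",
    "CountDistribution",
    "ssa_run",
    "steady_state_distribution",
    "fano",
    "cv",
    "hellinger",
]

SPECIES_SETS = ("nuclear_total", "cytoplasmic_total", "protein", "mrna_total")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Event-time sample path.

    ``states`` rows are (gene_state, M0N, MN_1..MN_S, MC_1..MC_R, P);
    the nascent species M0N is only populated when the delay is explicit.
    """

    times: np.ndarray
    states: np.ndarray
    seed: int
    model: GeneModel

    def __post_init__(self):
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be nondecreasing")


@dataclass(frozen=True)
class CountDistribution:
    """Probability mass function over molecule counts.

    ``n_samples`` is an effective sample count (number of arrivals that
    contributed, or inf for analytic distributions); ``batch_fano`` holds
    per-batch Fano estimates when the distribution came from ergodic
    averaging, enabling batch-means standard errors.
    """

    counts: np.ndarray
    pmf: np.ndarray
    n_samples: float = np.inf
    batch_fano: np.ndarray | None = None
    batch_mean: np.ndarray | None = None

    def __post_init__(self):
        s = float(np.sum(self.pmf))
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"pmf must sum to 1, got {s}")
        if np.any(self.pmf < -1e-15):
            raise ValueError("pmf entries must be nonnegative")

    def mean(self) -> float:
        return float(np.dot(self.counts, self.pmf))

    def var(self) -> float:
        mu = self.mean()
        return float(np.dot((self.counts - mu) ** 2, self.pmf))

    def fano(self) -> float:
        mu = self.mean()
        if mu <= 0:
            raise ValueError("Fano factor undefined for zero-mean distribution")
        return self.var() / mu

    def cv(self) -> float:
        mu = self.mean()
        if mu <= 0:
            raise ValueError("CV undefined for zero-mean distribution")
        return math.sqrt(self.var()) / mu

    def fano_se(self) -> float:
        """Batch-means Monte-Carlo standard error of the Fano factor."""
        return _batch_se(self.batch_fano)

    def mean_se(self) -> float:
        """Batch-means Monte-Carlo standard error of the mean."""
        return _batch_se(self.batch_mean)


def _batch_se(batches: np.ndarray | None) -> float:
    if batches is None or len(batches) < 2:
        raise ValueError("no batch information available")
    b = batches[np.isfinite(batches)]
    return float(np.std(b, ddof=1) / math.sqrt(len(b)))


def fano(dist: CountDistribution) -> float:
    """Variance/mean of a count distribution."""
    return dist.fano()


def cv(dist: CountDistribution) -> float:
    """Standard deviation/mean of a count distribution."""
    return dist.cv()


def hellinger(p: CountDistribution, q: CountDistribution) -> float:
    """Hellinger distance sqrt(1 - sum_m sqrt(p_m q_m)), in [0, 1].

    Supports are zero-padded to a common length; evaluated through the
    equivalent form H^2 = (1/2) sum (sqrt(p) - sqrt(q))^2, which stays
    accurate for nearly identical distributions.
    """
    n = max(len(p.pmf), len(q.pmf))
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[:len(p.pmf)] = p.pmf
    qq[:len(q.pmf)] = q.pmf
    h2 = 0.5 * float(np.sum((np.sqrt(pp) - np.sqrt(qq)) ** 2))
    return math.sqrt(min(max(h2, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Numba core: collapsed-delay SSA with time-weighted occupancy histograms
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ssa_histogram(G, S, R, kon, koff, k, delta, delta1, lam, lam1, lam2,
                   track, t_burn, t_max, n_batches, m_max, seed):  # pragma: no cover
    """Single-trajectory SSA accumulating a time-weighted count histogram.

    track: 0 nuclear total, 1 cytoplasmic total, 2 protein, 3 total mRNA.
    Species beyond the tracked compartment are not simulated (they are
    strictly downstream and cannot influence upstream statistics).
    Returns (hist[n_batches, m_max+1], n_arrivals).
    """
    np.random.seed(seed)
    need_cyto = track == 1 or track == 3
    need_prot = track == 2
    g = 0  # gene state 0..G
    mn = np.zeros(S, dtype=np.int64)
    mc = np.zeros(R, dtype=np.int64)
    p = 0
    tot_mn = 0
    tot_mc = 0
    hist = np.zeros((n_batches, m_max + 1))
    batch_len = (t_max - t_burn) / n_batches
    t = 0.0
    n_arrivals = 0
    while t < t_max:
        # propensities
        a_gene = 0.0
        if g == 0:
            a_gene = kon
        else:
            a_gene = k[g - 1]
            if g == 1:
                a_gene += koff
        a_nuc = 0.0
        if S > 1:
            a_nuc = delta * (tot_mn - mn[S - 1]) + delta1 * mn[S - 1]
        else:
            a_nuc = delta1 * mn[0]
        a_cyt = lam * tot_mc if (need_cyto or need_prot) else 0.0
        a_tr = lam1 * mc[0] if need_prot else 0.0
        a_dec = lam2 * p if need_prot else 0.0
        atot = a_gene + a_nuc + a_cyt + a_tr + a_dec
        if atot <= 0.0:
            break
        tau = np.random.exponential(1.0 / atot)
        # accumulate occupancy of the tracked total over [t, t+tau)
        if t + tau > t_burn:
            lo = t if t > t_burn else t_burn
            hi = t + tau if t + tau < t_max else t_max
            if track == 0:
                val = tot_mn
            elif track == 1:
                val = tot_mc
            elif track == 2:
                val = p
            else:
                val = tot_mn + tot_mc
            if val > m_max:
                val = m_max
            b = int((lo - t_burn) / batch_len)
            if b >= n_batches:
                b = n_batches - 1
            hist[b, val] += hi - lo
        t += tau
        if t >= t_max:
            break
        # choose reaction
        u = np.random.random() * atot
        if u < a_gene:
            if g == 0:
                g = 1
            elif g == 1 and koff > 0.0 and u < koff:
                g = 0
            elif g == G:
                g = 1
                mn[0] += 1
                tot_mn += 1
                n_arrivals += 1
            else:
                g += 1
        else:
            u -= a_gene
            if u < a_nuc:
                if S == 1:
                    mn[0] -= 1
                    tot_mn -= 1
                    if need_cyto or need_prot:
                        mc[0] += 1
                        tot_mc += 1
                else:
                    if u < delta1 * mn[S - 1]:
                        mn[S - 1] -= 1
                        tot_mn -= 1
                        if need_cyto or need_prot:
                            mc[0] += 1
                            tot_mc += 1
                    else:
                        u -= delta1 * mn[S - 1]
                        # pick the stage among 1..S-1 (rates delta*mn[s])
                        s = 0
                        acc = delta * mn[0]
                        while acc < u and s < S - 2:
                            s += 1
                            acc += delta * mn[s]
                        mn[s] -= 1
                        mn[s + 1] += 1
            else:
                u -= a_nuc
                if u < a_cyt:
                    r = 0
                    acc = lam * mc[0]
                    while acc < u and r < R - 1:
                        r += 1
                        acc += lam * mc[r]
                    mc[r] -= 1
                    tot_mc -= 1
                    if r < R - 1:
                        mc[r + 1] += 1
                        tot_mc += 1
                else:
                    u -= a_cyt
                    if u < a_tr:
                        p += 1
                    else:
                        p -= 1
    return hist, n_arrivals


# ---------------------------------------------------------------------------
# Python reference SSA (explicit delay queue, full state recording)
# ---------------------------------------------------------------------------

def ssa_run(m: GeneModel, t_max: float, seed: int,
            collapse_delay: bool = True, max_events: int = 2_000_000) -> Trajectory:
    """Exact SSA sample path recording every event (Python reference engine).

    With ``collapse_delay`` (default) the nascent-mRNA pair of steps is
    replaced by direct production of the first nuclear stage.  With it
    off, each nascent mRNA is held for the fixed elongation time
    ``T_elong`` in a priority queue of scheduled completions that are
    interleaved with the exponential events; exponential clocks are
    redrawn after every event, scheduled completions are not.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    G, S, R = m.G, m.S, m.R
    g = 0
    m0n = 0
    mn = np.zeros(S, dtype=int)
    mc = np.zeros(R, dtype=int)
    p = 0
    pending: list[float] = []  # completion times of delayed maturations
    times = [0.0]
    states = [(g, m0n, *mn, *mc, p)]
    t = 0.0

    def propensities():
        a = []
        if g == 0:
            a.append(("on", m.k_on))
        else:
            if g == 1:
                a.append(("off", m.k_off))
            a.append(("adv", m.k[g - 1]))
        for s in range(S - 1):
            a.append((("nuc", s), m.delta * mn[s]))
        a.append((("exp",), m.delta1 * mn[S - 1]))
        for r in range(R):
            a.append((("cyt", r), m.lam * mc[r]))
        a.append((("tr",), m.lam1 * mc[0]))
        a.append((("dec",), m.lam2 * p))
        return a

    for _ in range(max_events):
        props = propensities()
        atot = sum(w for _, w in props)
        tau = rng.exponential(1.0 / atot) if atot > 0 else math.inf
        t_next = t + tau
        if pending and pending[0] <= t_next:
            # delayed maturation fires first
            t = heapq.heappop(pending)
            m0n -= 1
            mn[0] += 1
        else:
            if not np.isfinite(t_next) or t_next > t_max:
                break
            t = t_next
            u = rng.random() * atot
            acc = 0.0
            for label, w in props:
                acc += w
                if u < acc:
                    break
            if label == "on":
                g = 1
            elif label == "off":
                g = 0
            elif label == "adv":
                if g == G:
                    g = 1
                    if collapse_delay or m.T_elong == 0.0:
                        mn[0] += 1
                    else:
                        m0n += 1
                        heapq.heappush(pending, t + m.T_elong)
                else:
                    g += 1
            elif label[0] == "nuc":
                mn[label[1]] -= 1
                mn[label[1] + 1] += 1
            elif label[0] == "exp":
                mn[S - 1] -= 1
                mc[0] += 1
            elif label[0] == "cyt":
                r = label[1]
                mc[r] -= 1
                if r < R - 1:
                    mc[r + 1] += 1
            elif label[0] == "tr":
                p += 1
            else:
                p -= 1
        times.append(t)
        states.append((g, m0n, *mn, *mc, p))
        if t >= t_max:
            break
    return Trajectory(times=np.asarray(times), states=np.asarray(states),
                      seed=seed, model=m)


def occupancy_distribution(traj: Trajectory, species_set: str,
                           t_burn: float = 0.0) -> CountDistribution:
    """Time-weighted count distribution of a summed species from a trajectory."""
    m = traj.model
    G, S, R = m.G, m.S, m.R
    sl = {"nuclear_total": slice(2, 2 + S),
          "cytoplasmic_total": slice(2 + S, 2 + S + R),
          "protein": slice(2 + S + R, 2 + S + R + 1),
          "mrna_total": slice(2, 2 + S + R)}[species_set]
    vals = traj.states[:-1, sl].sum(axis=1)
    dt = np.diff(traj.times)
    keep = traj.times[:-1] >= t_burn
    vals, dt = vals[keep], dt[keep]
    m_max = int(vals.max()) if len(vals) else 0
    hist = np.bincount(vals.astype(int), weights=dt, minlength=m_max + 1)
    return CountDistribution(counts=np.arange(len(hist)), pmf=hist / hist.sum(),
                             n_samples=float(len(vals)))


# ---------------------------------------------------------------------------
# Steady-state distributions by ergodic averaging
# ---------------------------------------------------------------------------

def _expected_scale(m: GeneModel, species_set: str) -> tuple[float, float]:
    """(mean, histogram cap) for the tracked total."""
    ss = steady_state_means(m)
    mu = {"nuclear_total": ss.MN.sum(),
          "cytoplasmic_total": ss.MC.sum(),
          "protein": ss.P,
          "mrna_total": ss.MN.sum() + ss.MC.sum()}[species_set]
    cap = int(mu + 25.0 * math.sqrt(mu + 1.0) + 80)
    return float(mu), cap


def steady_state_distribution(m: GeneModel, species_set: str,
                              t_max: float, seed: int,
                              t_burn: float | None = None,
                              n_batches: int = 20) -> CountDistribution:
    """Time-weighted steady-state distribution of a summed species.

    Runs one long collapsed-delay trajectory and accumulates the
    occupancy of the tracked total after the burn-in (default 10x the
    slowest relevant timescale).  Per-batch Fano estimates (20 batches by
    default) provide the Monte-Carlo standard error.
    """
    if species_set not in SPECIES_SETS:
        raise ValueError(f"species_set must be one of {SPECIES_SETS}")
    ts = timescales(m)
    blocks = {"nuclear_total": ("G", "N"),
              "cytoplasmic_total": ("G", "N", "C"),
              "mrna_total": ("G", "N", "C"),
              "protein": ("G", "N", "C", "P")}[species_set]
    slowest = max(np.max(ts.tau(b)) for b in blocks)
    if t_burn is None:
        t_burn = 10.0 * slowest
    if t_burn >= t_max:
        raise ValueError("t_burn must be smaller than t_max")
    if t_max - t_burn < 100.0 * slowest:
        logger.warning(
            "sampling horizon %.3g min is below 100x the slowest timescale "
            "(%.3g min); moments may be poorly converged", t_max - t_burn, slowest)
    _, cap = _expected_scale(m, species_set)
    track = {"nuclear_total": 0, "cytoplasmic_total": 1,
             "protein": 2, "mrna_total": 3}[species_set]
    hist, n_arr = _ssa_histogram(
        m.G, m.S, m.R, m.k_on, m.k_off, np.asarray(m.k), m.delta, m.delta1,
        m.lam, m.lam1, m.lam2, track, float(t_burn), float(t_max),
        int(n_batches), cap, int(seed) & 0x7FFFFFFF)
    counts = np.arange(cap + 1)
    weights = hist.sum(axis=0)
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("no post-burn-in sampling time accumulated")
    batch_fano = np.full(n_batches, np.nan)
    batch_mean = np.full(n_batches, np.nan)
    for b in range(n_batches):
        w = hist[b]
        wt = w.sum()
        if wt > 0:
            mu = np.dot(counts, w) / wt
            batch_mean[b] = mu
            if mu > 0:
                var = np.dot((counts - mu) ** 2, w) / wt
                batch_fano[b] = var / mu
    pmf = weights / total
    nz = np.nonzero(pmf)[0]
    hi = (nz[-1] + 1) if len(nz) else 1
    return CountDistribution(counts=counts[:hi], pmf=pmf[:hi],
                             n_samples=float(n_arr), batch_fano=batch_fano,
                             batch_mean=batch_mean)
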