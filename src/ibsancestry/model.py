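"""The ancestry hidden Markov model: parameters, transitions, emissions.

State space
-----------
Six states: three ancestry states AA, AB, BB (both homologues from the
low-diversity population A / one from each / both from B) and three skip
states sAA, sAB, sBB that absorb windows with too much missing data while
remembering the surrounding ancestry.

Transitions
-----------
Ancestry switches are driven by recombination since admixture. With g
generations, per-site recombination rate r and window size w, the
per-homologue per-window-step switch probability is R = 1-(1-g*r)^w. Genetic
drift lets the same ancestral recombination event be inherited on both
homologues of one individual; the per-site probability of that, z, follows
the Wright-Fisher second-moment recursion (closed form in
:func:`resample_prob_z`), aggregated per window as Z = 1-(1-z)^w.

Emissions
---------
Each ancestry state emits the window score x (see :mod:`.scoring`) under a
normal model whose mean and SD are derived from the nucleotide diversities
pi_A, pi_B, pi_AB, the panel sizes and the window size — either analytically
(delta method on binomial mismatch counts, including the covariance induced
by the hybrid's own lineage and by fixed inter-population differences) or by
Monte Carlo calibration against the synthetic-data generator, which is the
authoritative reference. Skip states emit only the SKIP sentinel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .popstats import DiversityEstimates

logger = logging.getLogger(__name__)

__all__ = [
    "STATES",
    "ANCESTRY_STATES",
    "ModelParams",
    "TransitionMatrix",
    "EmissionSpec",
    "resample_prob_z",
    "build_transitions",
    "build_emissions",
    "distribution_overlap",
    "max_pairwise_overlap",
    "separate_emissions",
    "minimum_window",
    "recommend_window_size",
    "WindowRecommendation",
]

ANCESTRY_STATES = ("AA", "AB", "BB")
STATES = ("AA", "AB", "BB", "sAA", "sAB", "sBB")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelParams:
    """All demographic and model scalars.

    g: generations since admixture; r: per-site per-generation recombination
    probability (1 cM/Mb by default); p: proportion of hybrid ancestry from
    population A (floored at 0.001); N: admixed population census size;
    w: window size in bp (may be None until chosen); a, b: reference panel
    sizes; diversity: nucleotide diversity estimates.
    """

    g: float
    p: float
    N: float
    a: int
    b: int
    diversity: DiversityEstimates
    w: int | None = None
    r: float = 1e-8
    skip_threshold: float = 0.25

    def __post_init__(self):
        if not (0.001 <= self.p < 1.0):
            raise ValueError(f"p={self.p} outside [0.001, 1)")
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0.0 < self.skip_threshold <= 1.0):
            raise ValueError("skip_threshold must be in (0, 1]")
        if self.a < 1 or self.b < 1:
            raise ValueError("panel sizes a, b must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.w is not None and self.w < 1:
            raise ValueError("w must be >= 1")

    def with_window(self, w: int) -> "ModelParams":
        return replace(self, w=w)


def resample_prob_z(N: float, g: float, r: float) -> float:
    """Probability of resampling the same ancestral recombination event twice.

    Recombination events since admixture are treated as alleles in a
    Wright-Fisher population of 2N chromosomes: about 2N*r new events arise
    per generation per site, each at initial frequency 1/(2N), and drift for
    the remaining generations. Summing the second moment E[x^2] over event
    cohorts gives the closed form

        z = r * ( g - (2N-1) * (1 - (1 - 1/(2N))^g) )

    which is exact under the neutral WF second-moment recursion; for g=1 it
    reduces to r/(2N). Monotone increasing in g and r, decreasing in N.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if g < 0:
        raise ValueError("g must be >= 0")
    # 1 - (1 - 1/(2N))^g via log1p/expm1: the naive power loses all precision
    # once 1/(2N) drops below ~1e-9
    one_minus_lam_g = -math.expm1(g * math.log1p(-1.0 / (2.0 * N))) if N > 0.5 else 1.0
    return r * (g - (2.0 * N - 1.0) * one_minus_lam_g)


@dataclass(frozen=True)
class TransitionMatrix:
    """6-state transition structure plus start and end probabilities."""

    states: tuple[str, ...]
    probs: np.ndarray  # (6, 6)
    start: np.ndarray  # (6,)
    end: np.ndarray  # (6,)
    s: float
    R: float
    Z: float

    def __post_init__(self):
        rows = self.probs.sum(axis=1) + self.end
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError(f"transition rows + end do not sum to 1: {rows}")
        if not math.isclose(float(self.start.sum()), 1.0, abs_tol=1e-12):
            raise ValueError("start vector does not sum to 1")
        if (self.probs < 0).any() or (self.probs > 1).any():
            raise ValueError("transition probability outside [0, 1]")


def build_transitions(params: ModelParams, n_windows: int, s: float) -> TransitionMatrix:
    """Construct the full 6-state transition matrix.

    Off-diagonal ancestry transitions combine two independent per-homologue
    recombination processes (probability R each, landing in population A with
    probability p) with the shared-drift term Z; each ancestry state moves to
    its own skip state with probability s, skip states self-loop with s and
    otherwise copy their parent ancestry state's cross transitions; the end
    probability from every state is 1/n_windows; diagonals are complements.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if not (0.0 <= s < 1.0):
        raise ValueError("skip probability s must be in [0, 1)")
    if params.w is None:
        raise ValueError("window size w is not set")
    g, r, w, p = params.g, params.r, params.w, params.p
    if g * r >= 1.0:
        raise ValueError("g*r >= 1: per-site recombination probability saturated")
    R = 1.0 - (1.0 - g * r) ** w
    z = resample_prob_z(params.N, g, r)
    Z = 1.0 - (1.0 - z) ** w
    q = 1.0 - p

    t = {
        ("AA", "BB"): R**2 * q**2 + Z * q,
        ("AA", "AB"): 2.0 * R * q * (1.0 - R * q),
        ("BB", "AA"): R**2 * p**2 + Z * p,
        ("BB", "AB"): 2.0 * R * p * (1.0 - R * p),
        ("AB", "AA"): R * p * (1.0 - R * q) + Z * p,
        ("AB", "BB"): R * q * (1.0 - R * p) + Z * q,
    }
    end_p = 1.0 / n_windows
    idx = {name: i for i, name in enumerate(STATES)}
    probs = np.zeros((6, 6))
    for (a_st, b_st), v in t.items():
        probs[idx[a_st], idx[b_st]] = v
    # ancestry -> own skip state
    for anc in ANCESTRY_STATES:
        probs[idx[anc], idx["s" + anc]] = s
    # skip states: self-loop s, copy parent's cross transitions, return to
    # parent by complement
    for anc in ANCESTRY_STATES:
        sk = idx["s" + anc]
        probs[sk, sk] = s
        for other in ANCESTRY_STATES:
            if other != anc:
                probs[sk, idx[other]] = t[(anc, other)]
    if any(v < 0.0 or v > 1.0 for v in t.values()) or any(
        t[(a_st, "AB")] + t[(a_st, "BB" if a_st == "AA" else "AA")] > 1.0
        for a_st in ("AA", "BB")
    ) or t[("AB", "AA")] + t[("AB", "BB")] > 1.0:
        raise ValueError(
            "ancestry-switch probabilities exceed 1; g*r*w is too large — "
            "use a smaller window size"
        )
    end = np.full(6, end_p)
    for i, name in enumerate(STATES):
        # complement entry: self-transition for ancestry states, return to the
        # parent ancestry state for skip states (both are zero before this)
        j = idx[name[1:]] if name.startswith("s") else i
        nondiag = probs[i].sum()
        if nondiag + end_p > 1.0:
            # degenerate competition with the skip and end mass (e.g. a
            # single-window scaffold, where end probability is 1): scale the
            # row; the relative transition structure is preserved
            probs[i] *= (1.0 - end_p) / nondiag
            probs[i, j] = 0.0
        else:
            probs[i, j] = 1.0 - nondiag - end_p
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError(
            "a transition probability fell outside [0, 1]; g*r*w is too large — "
            "use a smaller window size"
        )
    start = np.array([p**2, 2.0 * p * q, q**2, 0.0, 0.0, 0.0])
    return TransitionMatrix(states=STATES, probs=probs, start=start, end=end, s=s, R=R, Z=Z)


@dataclass(frozen=True)
class EmissionSpec:
    """Normal emission model per ancestry state, plus the SKIP sentinel rule."""

    mu: np.ndarray  # (3,) for AA, AB, BB
    sigma: np.ndarray  # (3,)
    mode: str  # "analytic" or "monte_carlo"
    shrink_count: int = 0

    def __post_init__(self):
        if (self.sigma <= 0).any():
            raise ValueError("emission SDs must be positive")

    def log_density(self, x: float) -> np.ndarray:
        """Log normal density of score x under each ancestry state."""
        zed = (x - self.mu) / self.sigma
        return -0.5 * zed**2 - np.log(self.sigma) - 0.5 * _LOG_2PI


def _state_site_params(div: DiversityEstimates) -> dict[str, dict[str, float]]:
    """Per-state per-site mismatch rates and covariances vs the two panels.

    Under the generative model, a site mismatches the hybrid against a
    reference through three kinds of events: the hybrid's own lineage
    mutation (rate e = pi_pop/2, shared across every comparison at that
    site), the reference's private mutation, and — for cross-population
    comparisons — a fixed inter-population difference (rate
    delta = pi_AB - (pi_A + pi_B)/2, shared across all comparisons to the
    other population). The shared components generate the between-reference
    covariances c_aa/c_bb and the cross-panel covariance c_ab used in the
    variance of the panel-averaged score.
    """
    e_a = div.pi_A / 2.0
    e_b = div.pi_B / 2.0
    delta = div.pi_AB - e_a - e_b
    if delta < 0:
        logger.warning(
            "pi_AB < (pi_A + pi_B)/2: populations are less diverged than their "
            "internal diversity; clamping the fixed-difference rate at 0"
        )
        delta = 0.0
    return {
        "AA": dict(d_a=div.pi_A, d_b=div.pi_AB, c_ab=e_a, v=e_a, w=e_b),
        "AB": dict(
            d_a=(div.pi_A + div.pi_AB) / 2.0,
            d_b=(div.pi_B + div.pi_AB) / 2.0,
            c_ab=(e_a + e_b) / 2.0,
            v=e_a,
            w=e_b,
        ),
        "BB": dict(d_a=div.pi_AB, d_b=div.pi_B, c_ab=e_b, v=e_a, w=e_b),
    }


def _poisson_pmf(lam: float, span: float = 10.0, pad: int = 15) -> np.ndarray:
    """Truncated Poisson pmf vector covering the bulk of the distribution."""
    from scipy.stats import poisson

    hi = int(math.ceil(lam + span * math.sqrt(max(lam, 1.0)))) + pad
    return poisson.pmf(np.arange(hi + 1), lam)


def _panel_rates(w: int, sp: dict[str, float]) -> dict[str, float]:
    """Poisson rates of the independent mismatch components per window.

    G: events on the hybrid's own (sampled) lineage, shared by every
    comparison; DA/DB: fixed inter-population difference sites, shared within
    one panel; V/W: each reference's private events.
    """
    return dict(
        g=w * sp["c_ab"],
        da=max(w * (sp["d_a"] - sp["c_ab"] - sp["v"]), 0.0),
        db=max(w * (sp["d_b"] - sp["c_ab"] - sp["w"]), 0.0),
        v=w * sp["v"],
        wr=w * sp["w"],
    )


def _side_conditional_moments(w: int, lam_private: float, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(E[ln t-bar | t], Var[ln t-bar | t]) over shared mismatch counts t.

    Conditional on t shared mismatches, each of the k references adds
    V ~ Poisson(lam_private) private mismatches and contributes a mean tract
    length t(m) = (w - m)/(m + 1) = (w + 1)/(m + 1) - 1. The moments of
    u = mean of 1/(t + V + 1) are exact Poisson sums; ln of the panel
    average is expanded to third order.
    """
    pv = _poisson_pmf(lam_private)
    v = np.arange(pv.size)
    t_max = int(math.ceil(3.0 * (lam_private + 10))) + 80
    t = np.arange(t_max + 1)
    inv = 1.0 / (t[:, None] + v[None, :] + 1.0)
    mu1 = inv @ pv
    mu2 = (inv**2) @ pv
    mu3 = (inv**3) @ pv
    var_u = (mu2 - mu1**2) / k
    # third central moment of a mean of k iid terms
    m3_u = (mu3 - 3.0 * mu1 * mu2 + 2.0 * mu1**3) / k**2
    m = (w + 1.0) * mu1 - 1.0
    s2 = (w + 1.0) ** 2 * var_u
    s3 = (w + 1.0) ** 3 * m3_u
    e_ln = np.log(m) - s2 / (2.0 * m**2) + s3 / (3.0 * m**3)
    v_ln = s2 / m**2 - s3 / m**3
    return e_ln, np.maximum(v_ln, 0.0), t_max


def _marginalize_panel_shared(e_ln: np.ndarray, v_ln: np.ndarray, lam_d: float, g_max: int):
    """Mix the conditional moments over the panel-shared component D.

    Returns, indexed by the cross-shared count g: the mean, the second raw
    moment of the conditional mean (for the D-induced variance), and the
    expected conditional variance.
    """
    pd_ = _poisson_pmf(lam_d)
    d = np.arange(pd_.size)
    g = np.arange(g_max + 1)
    idx = np.minimum(g[:, None] + d[None, :], e_ln.size - 1)
    mean = e_ln[idx] @ pd_
    raw2 = (e_ln[idx] ** 2) @ pd_
    var_in = v_ln[idx] @ pd_
    return mean, raw2, var_in


def _analytic_state_moments(w: int, sp: dict[str, float], a: int, b: int) -> tuple[float, float]:
    """(mu, sigma) of the window score under one ancestry state."""
    rates = _panel_rates(w, sp)
    e_a, v_a, tmax_a = _side_conditional_moments(w, rates["v"], a)
    e_b, v_b, tmax_b = _side_conditional_moments(w, rates["wr"], b)
    pg = _poisson_pmf(rates["g"])
    g_max = pg.size - 1
    if g_max + 1 > min(tmax_a, tmax_b):  # pragma: no cover - generous grids
        raise RuntimeError("Poisson grid too small")
    ma, ra2, va_in = _marginalize_panel_shared(e_a, v_a, rates["da"], g_max)
    mb, rb2, vb_in = _marginalize_panel_shared(e_b, v_b, rates["db"], g_max)
    ea_tot = float(ma @ pg)
    eb_tot = float(mb @ pg)
    var_a = float(ra2 @ pg) - float((ma @ pg)) ** 2 + float(va_in @ pg)
    var_b = float(rb2 @ pg) - float((mb @ pg)) ** 2 + float(vb_in @ pg)
    cov = float((ma * mb) @ pg) - ea_tot * eb_tot
    mu = ea_tot - eb_tot
    var_x = var_a + var_b - 2.0 * cov
    return mu, math.sqrt(max(var_x, 1e-12))


def build_emissions(
    params: ModelParams,
    mode: str = "analytic",
    rng: np.random.Generator | None = None,
    n_windows_mc: int = 2000,
) -> EmissionSpec:
    """Expected window-score distribution for each ancestry state.

    analytic: delta-method mean and SD from the diversity estimates (see
    :func:`_state_site_params`); errors if w is below the minimum bound.
    monte_carlo: simulates ``n_windows_mc`` windows per state with the
    synthetic-data generator and the real scorer, then fits mean and SD —
    self-consistent with scoring by construction.
    """
    div = params.diversity
    if params.w is None:
        raise ValueError("window size w is not set")
    if min(div.pi_A, div.pi_B, div.pi_AB) <= 0:
        raise ValueError("all diversity estimates must be > 0")
    w = params.w

    if mode == "analytic":
        w_min = minimum_window(div, params.a, params.b)
        if w < w_min:
            raise ValueError(
                f"window size {w} is below the minimum bound {w_min} "
                "(expected >= 10 IBS tracts per panel comparison)"
            )
        site = _state_site_params(div)
        mu = np.empty(3)
        sigma = np.empty(3)
        for i, state in enumerate(ANCESTRY_STATES):
            mu[i], sigma[i] = _analytic_state_moments(w, site[state], params.a, params.b)
        return EmissionSpec(mu=mu, sigma=sigma, mode="analytic")

    if mode == "monte_carlo":
        from . import simtruth  # deferred: simtruth orchestrates on top of this module

        rng = np.random.default_rng() if rng is None else rng
        mu = np.empty(3)
        sigma = np.empty(3)
        for i, state in enumerate(ANCESTRY_STATES):
            xs = simtruth.sample_state_scores(
                div, state, params.a, params.b, w, n_windows_mc, rng
            )
            mu[i] = float(np.mean(xs))
            sigma[i] = float(np.std(xs, ddof=1))
        return EmissionSpec(mu=mu, sigma=sigma, mode="monte_carlo")

    raise ValueError(f"unknown emission mode {mode!r}")


def distribution_overlap(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Overlap of two normal densities: integral of min(f1, f2).

    Numeric trapezoid integration over the joint ±8 SD support; absolute
    accuracy better than 1e-4. Equal distributions give 1, widely separated
    ones give 0.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    lo = min(mu1 - 8.0 * sd1, mu2 - 8.0 * sd2)
    hi = max(mu1 + 8.0 * sd1, mu2 + 8.0 * sd2)
    x = np.linspace(lo, hi, 16001)
    f1 = np.exp(-0.5 * ((x - mu1) / sd1) ** 2) / (sd1 * math.sqrt(2.0 * math.pi))
    f2 = np.exp(-0.5 * ((x - mu2) / sd2) ** 2) / (sd2 * math.sqrt(2.0 * math.pi))
    return float(np.trapezoid(np.minimum(f1, f2), x))


def max_pairwise_overlap(spec: EmissionSpec) -> float:
    pairs = [(0, 1), (0, 2), (1, 2)]
    return max(
        distribution_overlap(spec.mu[i], spec.sigma[i], spec.mu[j], spec.sigma[j])
        for i, j in pairs
    )


def separate_emissions(spec: EmissionSpec, threshold: float = 0.5, max_iter: int = 60) -> EmissionSpec:
    """Iteratively halve all three SDs until the max pairwise overlap < threshold.

    Used when a forced window size leaves the emission distributions too
    entangled; the shrink count is recorded on the returned spec and logged.
    """
    sigma = spec.sigma.copy()
    count = 0
    while count < max_iter:
        trial = EmissionSpec(mu=spec.mu, sigma=sigma, mode=spec.mode, shrink_count=spec.shrink_count + count)
        if max_pairwise_overlap(trial) < threshold:
            break
        sigma = sigma * 0.5
        count += 1
    else:
        logger.warning("emission SDs could not be separated after %d halvings", max_iter)
    if count:
        logger.info("emission SDs halved %d time(s) to separate the distributions", count)
    return EmissionSpec(mu=spec.mu, sigma=sigma, mode=spec.mode, shrink_count=spec.shrink_count + count)


def minimum_window(div: DiversityEstimates, a: int, b: int) -> int:
    """Smallest window with an expected >= 10 IBS tracts per panel comparison.

    Below this the normal approximation for the score breaks down.
    """
    d_vs_a = min(div.pi_A, (div.pi_A + div.pi_AB) / 2.0, div.pi_AB)
    d_vs_b = min(div.pi_B, (div.pi_B + div.pi_AB) / 2.0, div.pi_AB)
    return int(math.ceil(max(10.0 / (a * d_vs_a), 10.0 / (b * d_vs_b))))


@dataclass(frozen=True)
class WindowRecommendation:
    w: int
    spec: EmissionSpec
    overlaps: tuple[tuple[int, float], ...]
    satisfied: bool


def recommend_window_size(
    params: ModelParams, grid: Sequence[int] | None = None
) -> WindowRecommendation:
    """Choose the smallest window whose max pairwise emission overlap is <= 0.5.

    The default grid runs in 1 kb steps from the minimum bound to 100 kb.
    If no grid value satisfies the criterion, the largest is returned with a
    prominent warning: the populations may be insufficiently differentiated
    (low F_ST) for window-based ancestry scoring.
    """
    w_min = minimum_window(params.diversity, params.a, params.b)
    if grid is None:
        start = int(math.ceil(w_min / 1000.0)) * 1000
        grid = list(range(start, 100_001, 1000)) or [w_min]
    grid = sorted(int(w) for w in grid)
    grid = [w for w in grid if w >= w_min]
    if not grid:
        raise ValueError(f"no grid value reaches the minimum window bound {w_min}")
    overlaps = []
    for w in grid:
        spec = build_emissions(params.with_window(w), mode="analytic")
        ov = max_pairwise_overlap(spec)
        overlaps.append((w, ov))
        if ov <= 0.5:
            return WindowRecommendation(w=w, spec=spec, overlaps=tuple(overlaps), satisfied=True)
    logger.warning(
        "no window size up to %d reaches emission overlap <= 0.5 (max overlap %.3f); "
        "the ancestral populations may be insufficiently differentiated (low F_ST)",
        grid[-1], overlaps[-1][1],
    )
    spec = build_emissions(params.with_window(grid[-1]), mode="analytic")
    return WindowRecommendation(w=grid[-1], spec=spec, overlaps=tuple(overlaps), satisfied=False)
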