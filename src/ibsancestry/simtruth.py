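"""Synthetic hybrid genomes with known ancestry, and evaluation against truth.

Two simulation backends:

* a self-contained mosaic generator (:func:`simulate_mosaic` +
  :func:`materialize_sequences`): each hybrid haplotype is a Markov mosaic of
  A/B segments (switch rate g*r per base, stationary A fraction p, optionally
  diluted geometrically by per-generation replacement migration), converted
  into DNA by i.i.d.-site mutation calibrated to target nucleotide
  diversities. Fast, no external engine, used by unit tests and Monte Carlo
  emission calibration.
* a coalescent backend (:mod:`.coalescent`, msprime) reproducing a
  polar/brown-bear-like demography with genealogy-derived truth via the
  TMRCA rule (:func:`truth_from_trees`), used by the full validation runs.

Truth is compared to calls window-by-window: the true label of a window is
the majority vote of true-ancestry bases inside it (ties or no vote:
uncalled, excluded from evaluation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import scoring, seqio
from .popstats import DiversityEstimates
from .seqio import PseudoHaploidSeq

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "MosaicHaplotype",
    "TruthTrack",
    "EvaluationResult",
    "simulate_mosaic",
    "materialize_sequences",
    "sample_state_scores",
    "truth_from_trees",
    "read_segmented_newick",
    "evaluate",
    "reproduce_table1",
]

_CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)

# printed bear diversity values used as default simulation targets
BEAR_PI_A = 0.000615
BEAR_PI_B = 0.00233
BEAR_PI_AB = 0.003564


@dataclass(frozen=True)
class SimConfig:
    """Conditions for the self-contained simulation backend.

    Defaults follow the bear-like validation setting: 10 x 1 Mb chromosomes,
    admixture 1000 generations ago starting at 50/50, recombination 1 cM/Mb,
    the printed polar/brown diversity values, 5 references per population,
    and (for the migration variant) 0.001 per-generation replacement by
    unadmixed B migrants.
    """

    L: int = 1_000_000
    n_chrom: int = 10
    n_hybrids: int = 1
    p_sim: float = 0.5
    g_sim: float = 1000.0
    r_sim: float = 1e-8
    pi_a: float = BEAR_PI_A
    pi_b: float = BEAR_PI_B
    pi_ab: float = BEAR_PI_AB
    a_panel: int = 5
    b_panel: int = 5
    migration_rate: float = 0.0
    outgroup_divergence: float = 3.0 * BEAR_PI_AB
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.migration_rate < 1.0):
            raise ValueError("migration_rate must be in [0, 1)")
        for name in ("pi_a", "pi_b", "pi_ab"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")

    @property
    def p_effective(self) -> float:
        """Present-day expected A fraction after geometric migrant dilution."""
        return self.p_sim * (1.0 - self.migration_rate) ** self.g_sim


@dataclass(frozen=True)
class MosaicHaplotype:
    """Ordered A/B ancestry segments partitioning [0, length).

    Adjacent segments differ in origin; ``n_breakpoints`` counts the raw
    recombination re-draw events (a re-drawn origin may equal the previous
    one, in which case the segments are merged but the event is counted).
    """

    segments: tuple[tuple[int, int, str], ...]
    length: int
    n_breakpoints: int = 0

    def origin_at(self, pos: int) -> str:
        for s, e, o in self.segments:
            if s <= pos < e:
                return o
        raise IndexError(pos)

    def a_fraction(self) -> float:
        return sum(e - s for s, e, o in self.segments if o == "A") / self.length


@dataclass(frozen=True)
class TruthTrack:
    """Known ancestry intervals; labels AA/AB/BB or 'none' (uncalled)."""

    intervals: tuple[tuple[int, int, str], ...]

    @property
    def length(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0


def _merge_labeled(intervals: Iterable[tuple[int, int, str]]) -> tuple[tuple[int, int, str], ...]:
    merged: list[list] = []
    for s, e, lab in intervals:
        if merged and merged[-1][2] == lab and merged[-1][1] == s:
            merged[-1][1] = e
        else:
            merged.append([s, e, lab])
    return tuple((s, e, l) for s, e, l in merged)


def _sample_mosaic(L: int, g: float, r: float, p_eff: float, rng: np.random.Generator) -> MosaicHaplotype:
    switch_prob = 1.0 - (1.0 - r) ** g
    n_break = rng.binomial(L - 1, switch_prob)
    cuts = np.sort(rng.choice(np.arange(1, L), size=n_break, replace=False)) if n_break else np.empty(0, int)
    bounds = np.concatenate(([0], cuts, [L]))
    origins = np.where(rng.random(len(bounds) - 1) < p_eff, "A", "B")
    segs = _merge_labeled(
        (int(bounds[i]), int(bounds[i + 1]), str(origins[i])) for i in range(len(origins))
    )
    return MosaicHaplotype(segments=segs, length=L, n_breakpoints=int(n_break))


def truth_from_haplotypes(hap1: MosaicHaplotype, hap2: MosaicHaplotype) -> TruthTrack:
    """Intersect two haplotypes' segments into AA/AB/BB intervals."""
    if hap1.length != hap2.length:
        raise ValueError("haplotype lengths differ")
    bounds = sorted({b for hap in (hap1, hap2) for s, e, _ in hap.segments for b in (s, e)})
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        o1, o2 = hap1.origin_at(s), hap2.origin_at(s)
        lab = "AA" if o1 == o2 == "A" else "BB" if o1 == o2 == "B" else "AB"
        out.append((s, e, lab))
    return TruthTrack(intervals=_merge_labeled(out))


@dataclass(frozen=True)
class HybridMosaic:
    """One hybrid chromosome: its two haplotype mosaics and derived truth."""

    hap1: MosaicHaplotype
    hap2: MosaicHaplotype
    truth: TruthTrack


def simulate_mosaic(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[list[HybridMosaic]]:
    """Draw ancestry mosaics for every hybrid and chromosome.

    Returns ``out[hybrid][chromosome]``. Deterministic under ``cfg.seed``
    when no generator is passed.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p_eff = cfg.p_effective
    out = []
    for _ in range(cfg.n_hybrids):
        per_chrom = []
        for _ in range(cfg.n_chrom):
            h1 = _sample_mosaic(cfg.L, cfg.g_sim, cfg.r_sim, p_eff, rng)
            h2 = _sample_mosaic(cfg.L, cfg.g_sim, cfg.r_sim, p_eff, rng)
            per_chrom.append(HybridMosaic(hap1=h1, hap2=h2, truth=truth_from_haplotypes(h1, h2)))
        out.append(per_chrom)
    return out


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Replace a Bernoulli(rate) subset of sites with a different base."""
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size, dtype=np.uint8)) % 4
    return out


def _to_seq(name: str, codes: np.ndarray) -> PseudoHaploidSeq:
    return PseudoHaploidSeq(name=name, bases=_CODE_TO_ASCII[codes])


def _pseudo_haploid_codes(c1: np.ndarray, c2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    take1 = rng.integers(0, 2, size=c1.size, dtype=np.uint8).astype(bool)
    return np.where(take1, c1, c2)


@dataclass
class SequenceSet:
    """Materialized pseudo-haploid genomes: hybrids, panels, outgroup."""

    hybrids: list[dict[str, PseudoHaploidSeq]]
    panel_a: list[dict[str, PseudoHaploidSeq]]
    panel_b: list[dict[str, PseudoHaploidSeq]]
    outgroup: dict[str, PseudoHaploidSeq]


def materialize_sequences(
    cfg: SimConfig,
    mosaics: list[list[HybridMosaic]],
    rng: np.random.Generator | None = None,
) -> SequenceSet:
    """Convert ancestry mosaics into pseudo-haploid DNA sequences.

    Population sequences S_A and S_B each diverge from a shared ancestral
    sequence at rate delta/2, with delta = pi_AB - (pi_A + pi_B)/2, so the
    realized cross-population mismatch rate is ~pi_AB and the outgroup
    (diverging from the shared ancestor at ``cfg.outgroup_divergence``)
    carries the ancestral allele at most population-specific difference
    sites — which is what makes ABBA/BABA polarization informative. Each
    sampled chromosome adds private mutations at rate pi_pop/2, giving
    within-population mismatch ~pi_pop. Hybrid haplotypes copy population
    chromosome draws segment-by-segment; everything is pseudo-haploidized.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    e_a, e_b = cfg.pi_a / 2.0, cfg.pi_b / 2.0
    delta = cfg.pi_ab - e_a - e_b
    if delta < 0:
        logger.warning("pi_AB < (pi_A + pi_B)/2; clamping fixed-difference rate at 0")
        delta = 0.0

    n_hyb = len(mosaics)
    hybrids: list[dict] = [dict() for _ in range(n_hyb)]
    panel_a: list[dict] = [dict() for _ in range(cfg.a_panel)]
    panel_b: list[dict] = [dict() for _ in range(cfg.b_panel)]
    outgroup: dict[str, PseudoHaploidSeq] = {}

    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        anc = rng.integers(0, 4, size=cfg.L, dtype=np.uint8)
        s_a = _mutate(anc, delta / 2.0, rng)
        s_b = _mutate(anc, delta / 2.0, rng)
        for i in range(cfg.a_panel):
            ph = _pseudo_haploid_codes(_mutate(s_a, e_a, rng), _mutate(s_a, e_a, rng), rng)
            panel_a[i][chrom] = _to_seq(chrom, ph)
        for i in range(cfg.b_panel):
            ph = _pseudo_haploid_codes(_mutate(s_b, e_b, rng), _mutate(s_b, e_b, rng), rng)
            panel_b[i][chrom] = _to_seq(chrom, ph)
        outgroup[chrom] = _to_seq(chrom, _mutate(anc, cfg.outgroup_divergence, rng))
        for h in range(n_hyb):
            haps = []
            for hap in (mosaics[h][c].hap1, mosaics[h][c].hap2):
                chrom_a = _mutate(s_a, e_a, rng)
                chrom_b = _mutate(s_b, e_b, rng)
                codes = np.empty(cfg.L, dtype=np.uint8)
                for s, e, origin in hap.segments:
                    src = chrom_a if origin == "A" else chrom_b
                    codes[s:e] = src[s:e]
                haps.append(codes)
            hybrids[h][chrom] = _to_seq(chrom, _pseudo_haploid_codes(haps[0], haps[1], rng))
    return SequenceSet(hybrids=hybrids, panel_a=panel_a, panel_b=panel_b, outgroup=outgroup)


def sample_state_scores(
    div: DiversityEstimates,
    state: str,
    a: int,
    b: int,
    w: int,
    n_windows: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Realized window scores under a fixed ancestry state (Monte Carlo).

    Generates hybrid + panel windows from the generative model of
    :func:`materialize_sequences` with the hybrid held in ``state`` and runs
    the real scorer; used for emission calibration and as a test oracle.
    """
    if state not in ("AA", "AB", "BB"):
        raise ValueError(f"unknown ancestry state {state!r}")
    e_a, e_b = div.pi_A / 2.0, div.pi_B / 2.0
    delta = max(div.pi_AB - e_a - e_b, 0.0)
    xs: list[float] = []
    chunk = max(1, min(n_windows, 200))
    remaining = n_windows
    while remaining > 0:
        k = min(chunk, remaining)
        L = k * w
        anc = rng.integers(0, 4, size=L, dtype=np.uint8)
        s_a = _mutate(anc, delta / 2.0, rng)
        s_b = _mutate(anc, delta / 2.0, rng)
        hap_pops = {"AA": ("A", "A"), "AB": ("A", "B"), "BB": ("B", "B")}[state]
        haps = [
            _mutate(s_a, e_a, rng) if popn == "A" else _mutate(s_b, e_b, rng)
            for popn in hap_pops
        ]
        hybrid = _to_seq("mc", _pseudo_haploid_codes(haps[0], haps[1], rng))
        refs_a = [
            _to_seq(f"A{i}", _pseudo_haploid_codes(_mutate(s_a, e_a, rng), _mutate(s_a, e_a, rng), rng))
            for i in range(a)
        ]
        refs_b = [
            _to_seq(f"B{i}", _pseudo_haploid_codes(_mutate(s_b, e_b, rng), _mutate(s_b, e_b, rng), rng))
            for i in range(b)
        ]
        scores, _ = scoring.score_scaffold(hybrid, refs_a, refs_b, w, skip_threshold=1.0)
        xs.extend(sc.x for sc in scores if not sc.is_skip)
        remaining -= k
    return np.asarray(xs)


# ---------------------------------------------------------------------------
# genealogy-derived truth (TMRCA rule)
# ---------------------------------------------------------------------------

def _node_ages(tree: dendropy.Tree) -> dict:
    ages: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(ages[ch] + (ch.edge.length or 0.0) for ch in node.child_nodes())
    return ages


def _tmrca(tree: dendropy.Tree, ages: dict, labels: set[str]) -> float:
    mrca = tree.mrca(taxon_labels=list(labels))
    return ages[mrca]


def truth_from_trees(
    trees: Sequence[tuple[int, int, "dendropy.Tree | str"]],
    pop_a_tips: Sequence[str],
    pop_b_tips: Sequence[str],
    split_time: float,
    hybrid_pairs: Sequence[tuple[str, str]],
) -> list[TruthTrack]:
    """Label hybrid haplotype segments by the TMRCA rule.

    For each genomic segment (one genealogy per segment) and each hybrid
    haplotype: the haplotype has population-A (introgressor) origin iff its
    TMRCA with all A tips is more recent than its TMRCA with all B tips AND
    more recent than the A/B population split (strict inequalities,
    separating true introgression from incomplete lineage sorting);
    otherwise it has population-B origin — B is the non-introgressed
    default, so incompletely sorted lineages count as B rather than as
    introgressed. Exact TMRCA ties leave the segment uncalled. The two
    haplotype origins combine to AA/AB/BB, or 'none' when either is
    uncalled.
    """
    parsed: list[tuple[int, int, dendropy.Tree]] = []
    tns = dendropy.TaxonNamespace()
    for start, end, tree in trees:
        if isinstance(tree, str):
            tree = dendropy.Tree.get(
                data=tree, schema="newick", taxon_namespace=tns, rooting="force-rooted"
            )
        tree.is_rooted = True
        parsed.append((start, end, tree))

    out = []
    for tip1, tip2 in hybrid_pairs:
        intervals = []
        for start, end, tree in parsed:
            ages = _node_ages(tree)
            origins = []
            for tip in (tip1, tip2):
                t_a = _tmrca(tree, ages, set(pop_a_tips) | {tip})
                t_b = _tmrca(tree, ages, set(pop_b_tips) | {tip})
                if t_a == t_b:
                    origins.append(None)
                elif t_a < t_b and t_a < split_time:
                    origins.append("A")
                else:
                    origins.append("B")
            if None in origins:
                lab = "none"
            elif origins[0] == origins[1]:
                lab = origins[0] * 2
            else:
                lab = "AB"
            intervals.append((start, end, lab))
        out.append(TruthTrack(intervals=_merge_labeled(sorted(intervals))))
    return out


def read_segmented_newick(path: str | Path) -> list[tuple[int, int, str]]:
    """Read 'start<TAB>end<TAB>newick' lines: one genealogy per segment."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            start, end, newick = line.split("\t", 2)
            out.append((int(start), int(end), newick))
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

_LABELS = ("AA", "AB", "BB")


@dataclass
class EvaluationResult:
    """Windowed confusion counts call x truth, poolable with ``+``."""

    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    def __add__(self, other: "EvaluationResult") -> "EvaluationResult":
        merged = dict(self.confusion)
        for k, v in other.confusion.items():
            merged[k] = merged.get(k, 0) + v
        return EvaluationResult(confusion=merged)

    @property
    def n_windows(self) -> int:
        return sum(self.confusion.values())

    def prop_calls_correct(self, state: str) -> float:
        called = sum(v for (c, t), v in self.confusion.items() if c == state)
        correct = self.confusion.get((state, state), 0)
        return correct / called if called else float("nan")

    def prop_truth_detected(self, state: str) -> float:
        truth = sum(v for (c, t), v in self.confusion.items() if t == state)
        correct = self.confusion.get((state, state), 0)
        return correct / truth if truth else float("nan")

    @property
    def overall_accuracy(self) -> float:
        if not self.n_windows:
            raise ValueError("zero evaluable windows")
        correct = sum(v for (c, t), v in self.confusion.items() if c == t)
        return correct / self.n_windows

    def average_precision(self) -> float:
        return float(np.nanmean([self.prop_calls_correct(s) for s in _LABELS]))

    def average_recall(self) -> float:
        return float(np.nanmean([self.prop_truth_detected(s) for s in _LABELS]))


def _windowed_labels(intervals: Sequence[tuple[int, int, str]], w: int, n_win: int) -> list[str | None]:
    """Majority-vote label per window; None where uncalled or tied."""
    votes = np.zeros((n_win, 3), dtype=np.int64)
    lab_idx = {lab: i for i, lab in enumerate(_LABELS)}
    for s, e, lab in intervals:
        if lab not in lab_idx:
            continue
        first = s // w
        last = (e - 1) // w
        for k in range(first, min(last, n_win - 1) + 1):
            lo, hi = max(s, k * w), min(e, (k + 1) * w)
            if hi > lo:
                votes[k, lab_idx[lab]] += hi - lo
    out: list[str | None] = []
    for k in range(n_win):
        row = votes[k]
        if row.sum() == 0:
            out.append(None)
            continue
        best = row.max()
        winners = np.flatnonzero(row == best)
        out.append(_LABELS[winners[0]] if winners.size == 1 else None)
    return out


def evaluate(calls, truth: TruthTrack, w: int) -> EvaluationResult:
    """Compare an ancestry call track to truth on one scaffold.

    ``calls`` is an AncestryTrack (or a bare interval sequence). Truth is
    discretized to windows by majority vote; windows with uncalled truth are
    excluded. Raises if no window is evaluable.
    """
    call_intervals = getattr(calls, "intervals", calls)
    if not call_intervals:
        raise ValueError("empty call track")
    n_win = min(max(e for _, e, _ in call_intervals), truth.length) // w
    if n_win == 0:
        raise ValueError("no whole window covered by both calls and truth")
    call_lab = _windowed_labels(call_intervals, w, n_win)
    truth_lab = _windowed_labels(truth.intervals, w, n_win)
    confusion: dict[tuple[str, str], int] = {}
    for c, t in zip(call_lab, truth_lab):
        if c is None or t is None:
            continue
        confusion[(c, t)] = confusion.get((c, t), 0) + 1
    result = EvaluationResult(confusion=confusion)
    if result.n_windows == 0:
        raise ValueError("zero evaluable windows (no truth-labeled window overlaps the calls)")
    return result


# ---------------------------------------------------------------------------
# full validation loop
# ---------------------------------------------------------------------------

def _run_validation_replicate(seqset: SequenceSet, truths, w: int, g: float, N: float):
    """Shared inner loop: estimate parameters, run the pipeline, evaluate."""
    from . import infer, popstats  # deferred: avoid import cycle at module load
    from .model import ModelParams, build_emissions

    pi_a = popstats.population_pi(seqset.panel_a)
    pi_b = popstats.population_pi(seqset.panel_b)
    pi_ab = popstats.cross_population_pi(seqset.panel_a, seqset.panel_b)
    div = DiversityEstimates(pi_A=min(pi_a, pi_b), pi_B=max(pi_a, pi_b), pi_AB=pi_ab)
    pooled = EvaluationResult()
    proportions = []
    for h, hybrid in enumerate(seqset.hybrids):
        fh = popstats.f_hat(
            seqset.panel_b[0], hybrid, seqset.panel_a[0], seqset.panel_a[1], seqset.outgroup
        )
        params = ModelParams(g=g, p=fh.p_used, N=N, a=len(seqset.panel_a), b=len(seqset.panel_b), diversity=div, w=w)
        emissions = build_emissions(params, mode="analytic")
        tracks, summary, _ = infer.run_hybrid(
            hybrid, seqset.panel_a, seqset.panel_b, params, hybrid_name=f"H{h+1}", emissions=emissions
        )
        for track in tracks:
            pooled = pooled + evaluate(track, truths[h][track.scaffold], w)
        proportions.append((summary.proportion, fh.p_used))
    return pooled, proportions


def reproduce_table1(
    scale: int = 5,
    engine: str = "auto",
    w: int = 10_000,
    seed: int = 0,
    n_refs: int = 5,
    models: Sequence[str] = ("migration", "single_pulse"),
) -> tuple[pd.DataFrame, dict[str, EvaluationResult]]:
    """Run the full simulation-validation protocol and tabulate accuracy.

    Per replicate: simulate 10 x 1 Mb chromosomes for 5 hybrids plus
    ``n_refs`` references per population and an outgroup, estimate nucleotide
    diversities and per-hybrid admixture proportion (f-hat), run the ancestry
    pipeline at window size ``w`` with g=1000 and N=3000, and score calls
    against genealogy-derived truth. ``scale`` is the replicate count per
    demographic model. The coalescent engine (msprime) is preferred; the
    mosaic backend is the fallback.
    """
    if engine == "auto":
        try:
            from . import coalescent  # noqa: F401
            engine = "coalescent"
        except ImportError:  # pragma: no cover
            engine = "mosaic"
    rng = np.random.default_rng(seed)
    pooled: dict[str, EvaluationResult] = {}
    for model in models:
        if model not in ("migration", "single_pulse"):
            raise ValueError(f"unknown demographic model {model!r}")
        acc = EvaluationResult()
        for _ in range(scale):
            rep_seed = int(rng.integers(1, 2**31 - 1))
            if engine == "coalescent":
                from . import coalescent

                rep = coalescent.simulate_bear_replicate(model=model, seed=rep_seed, n_refs=n_refs)
                seqset = SequenceSet(
                    hybrids=rep.hybrids, panel_a=rep.polar, panel_b=rep.brown, outgroup=rep.outgroup
                )
                truths = rep.truths
            elif engine == "mosaic":
                cfg = SimConfig(
                    n_hybrids=5, a_panel=n_refs, b_panel=n_refs,
                    migration_rate=0.001 if model == "migration" else 0.0,
                    seed=rep_seed,
                )
                mosaics = simulate_mosaic(cfg)
                seqset = materialize_sequences(cfg, mosaics)
                truths = [
                    {f"chr{c + 1}": mosaics[h][c].truth for c in range(cfg.n_chrom)}
                    for h in range(cfg.n_hybrids)
                ]
            else:
                raise ValueError(f"unknown engine {engine!r}")
            rep_eval, _ = _run_validation_replicate(seqset, truths, w=w, g=1000.0, N=3000.0)
            acc = acc + rep_eval
        pooled[model] = acc

    rows = []
    for model, ev in pooled.items():
        pretty = "Migration" if model == "migration" else "Single-pulse"
        for state in _LABELS:
            rows.append(
                dict(model=pretty, state=state,
                     prop_calls_correct=ev.prop_calls_correct(state),
                     prop_truth_detected=ev.prop_truth_detected(state))
            )
        rows.append(dict(model=pretty, state="Average",
                         prop_calls_correct=ev.average_precision(),
                         prop_truth_detected=ev.average_recall()))
        rows.append(dict(model=pretty, state="Overall accuracy",
                         prop_calls_correct=ev.overall_accuracy,
                         prop_truth_detected=float("nan")))
    return pd.DataFrame(rows), pooled
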