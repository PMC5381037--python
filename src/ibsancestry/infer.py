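"""Decode window scores into ancestry tracts and orchestrate whole runs.

Decoding is Viterbi over the six states in log space: ancestry states emit
real scores under their normal emission density and cannot emit the SKIP
sentinel; skip states emit only SKIP. Windows decoded into skip states are
reported with their parent ancestry label and flagged as imputed.

The global admixture proportion of a decoded genome is

    (2 * bases_AA + bases_AB) / (2 * bases_labeled)

i.e. the fraction of homologous chromosomes carrying population-A ancestry.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import popstats, scoring, seqio
from .model import ANCESTRY_STATES, STATES, EmissionSpec, ModelParams, TransitionMatrix
from .model import build_emissions, build_transitions, max_pairwise_overlap, recommend_window_size, separate_emissions
from .popstats import DiversityEstimates
from .scoring import WindowScore
from .seqio import GenomeWindow, PseudoHaploidSeq

logger = logging.getLogger(__name__)

__all__ = [
    "AncestryTrack",
    "DecodedPath",
    "RunSummary",
    "decode",
    "path_log_probability",
    "path_to_track",
    "admixture_proportion",
    "infer_scaffold",
    "run_hybrid",
    "run",
]

_NEG_INF = -math.inf


@dataclass(frozen=True)
class DecodedPath:
    """Viterbi result: raw 6-state path, ancestry labels, imputed flags."""

    states: tuple[str, ...]
    labels: tuple[str, ...]
    imputed: tuple[bool, ...]


@dataclass(frozen=True)
class AncestryTrack:
    """Per-scaffold ancestry intervals (sorted, non-overlapping, merged)."""

    scaffold: str
    intervals: tuple[tuple[int, int, str], ...]

    def bed_rows(self) -> list[tuple[str, int, int, str]]:
        return [(self.scaffold, s, e, lab) for s, e, lab in self.intervals]


@dataclass
class RunSummary:
    """Per-hybrid run summary: proportion, state base counts, parameters."""

    hybrid: str
    proportion: float
    bases: dict[str, int]
    s: float
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "hybrid": self.hybrid,
                "admixture_proportion": self.proportion,
                "bases": self.bases,
                "skip_fraction": self.s,
                "params": self.params,
            },
            indent=2,
        )


def _emission_logs(score: WindowScore, emissions: EmissionSpec) -> np.ndarray:
    """Log emission probability of one window under each of the 6 states."""
    out = np.full(6, _NEG_INF)
    if score.is_skip:
        out[3:] = 0.0
    else:
        out[:3] = emissions.log_density(score.x)
    return out


def _start_logs(transitions: TransitionMatrix, first_is_skip: bool) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logs = np.log(transitions.start)
    if first_is_skip:
        # degenerate input: a scaffold beginning with a skipped window; let
        # each skip state inherit its parent ancestry state's start mass
        logs[3:] = logs[:3]
    return logs


def path_log_probability(
    states_seq: Sequence[int],
    scores: Sequence[WindowScore],
    transitions: TransitionMatrix,
    emissions: EmissionSpec,
) -> float:
    """Joint log probability of one 6-state path (indices into STATES).

    This is the scoring contract shared by the Viterbi decoder and any
    exhaustive-enumeration cross-check.
    """
    if len(states_seq) != len(scores):
        raise ValueError("path and score lengths differ")
    start = _start_logs(transitions, scores[0].is_skip)
    with np.errstate(divide="ignore"):
        trans = np.log(transitions.probs)
        end = np.log(transitions.end)
    total = start[states_seq[0]] + _emission_logs(scores[0], emissions)[states_seq[0]]
    for t in range(1, len(scores)):
        total += trans[states_seq[t - 1], states_seq[t]]
        total += _emission_logs(scores[t], emissions)[states_seq[t]]
    total += end[states_seq[-1]]
    return float(total)


def decode(
    scores: Sequence[WindowScore],
    transitions: TransitionMatrix,
    emissions: EmissionSpec,
) -> DecodedPath:
    """Most likely 6-state path for a scaffold's window scores (Viterbi).

    Ties are broken toward the earlier state in the fixed order
    AA < AB < BB < sAA < sAB < sBB. Raises if every window is skipped.
    """
    n = len(scores)
    if n == 0:
        raise ValueError("no windows to decode")
    if all(sc.is_skip for sc in scores):
        raise ValueError("every window is skipped; nothing to decode")

    with np.errstate(divide="ignore"):
        ltrans = np.log(transitions.probs)
        lend = np.log(transitions.end)
    delta = _start_logs(transitions, scores[0].is_skip) + _emission_logs(scores[0], emissions)
    back = np.zeros((n, 6), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + ltrans  # (from, to)
        best_from = np.argmax(cand, axis=0)  # first max wins ties
        delta = cand[best_from, np.arange(6)] + _emission_logs(scores[t], emissions)
        back[t] = best_from
    delta = delta + lend
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    if not np.isfinite(delta[path[-1]]):
        raise ValueError("no admissible state path (all log probabilities -inf)")
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    names = tuple(STATES[i] for i in path)
    labels = tuple(name[1:] if name.startswith("s") else name for name in names)
    imputed = tuple(name.startswith("s") for name in names)
    return DecodedPath(states=names, labels=labels, imputed=imputed)


def path_to_track(path: Sequence[str], windows: Sequence[GenomeWindow]) -> AncestryTrack:
    """Merge per-window labels into maximal same-label intervals."""
    if len(path) != len(windows):
        raise ValueError("path and window lists differ in length")
    if not windows:
        return AncestryTrack(scaffold="", intervals=())
    scaffold = windows[0].scaffold
    intervals: list[list] = []
    for label, win in zip(path, windows):
        if intervals and intervals[-1][2] == label and intervals[-1][1] == win.start:
            intervals[-1][1] = win.end
        else:
            intervals.append([win.start, win.end, label])
    return AncestryTrack(scaffold=scaffold, intervals=tuple((s, e, l) for s, e, l in intervals))


def admixture_proportion(tracks: Sequence[AncestryTrack]) -> float:
    """(2*AA bases + AB bases) / (2 * labeled bases) over all scaffolds."""
    bases = {lab: 0 for lab in ANCESTRY_STATES}
    for track in tracks:
        for s, e, lab in track.intervals:
            bases[lab] += e - s
    total = sum(bases.values())
    if total == 0:
        raise ValueError("no labeled bases")
    return (2 * bases["AA"] + bases["AB"]) / (2 * total)


def infer_scaffold(
    hybrid: PseudoHaploidSeq,
    refs_a: Sequence[PseudoHaploidSeq],
    refs_b: Sequence[PseudoHaploidSeq],
    params: ModelParams,
    emissions: EmissionSpec,
    s: float,
) -> tuple[AncestryTrack, DecodedPath, list[WindowScore]]:
    """Score and decode one scaffold with a genome-wide skip fraction ``s``."""
    scores, _ = scoring.score_scaffold(hybrid, refs_a, refs_b, params.w, params.skip_threshold)
    transitions = build_transitions(params, n_windows=len(scores), s=s)
    path = decode(scores, transitions, emissions)
    track = path_to_track(path.labels, [sc.window for sc in scores])
    return track, path, scores


def _genome_skip_fraction(
    hybrids_scaffolds: Mapping[str, PseudoHaploidSeq], w: int, skip_threshold: float
) -> float:
    n_skip = n_tot = 0
    for seq in hybrids_scaffolds.values():
        for win in seqio.tile_windows(seq, w):
            n_tot += 1
            n_skip += win.n_fraction > skip_threshold
    if n_tot == 0:
        raise ValueError("no whole windows on any scaffold")
    return n_skip / n_tot


def run_hybrid(
    hybrid: Mapping[str, PseudoHaploidSeq],
    refs_a: Sequence[Mapping[str, PseudoHaploidSeq]],
    refs_b: Sequence[Mapping[str, PseudoHaploidSeq]],
    params: ModelParams,
    hybrid_name: str = "hybrid",
    emissions: EmissionSpec | None = None,
) -> tuple[list[AncestryTrack], RunSummary, dict[str, DecodedPath]]:
    """Infer ancestry for one hybrid across all of its scaffolds.

    ``hybrid`` and each reference are mappings scaffold -> sequence; only
    scaffolds present in the hybrid and in every reference are used (missing
    ones are dropped with a warning). The skip fraction s is computed
    genome-wide, and the per-scaffold transition matrices use each scaffold's
    own window count.
    """
    if params.w is None:
        raise ValueError("window size w must be set (see recommend_window_size)")
    usable = {}
    for name, seq in hybrid.items():
        if all(name in ref for ref in list(refs_a) + list(refs_b)) and seq.length >= params.w:
            usable[name] = seq
        else:
            logger.warning("scaffold %s dropped (absent from a reference or too short)", name)
    if not usable:
        raise ValueError("no scaffold is shared by the hybrid and every reference")

    s = _genome_skip_fraction(usable, params.w, params.skip_threshold)
    if emissions is None:
        emissions = build_emissions(params, mode="analytic")
    if max_pairwise_overlap(emissions) > 0.5:
        emissions = separate_emissions(emissions)

    tracks: list[AncestryTrack] = []
    paths: dict[str, DecodedPath] = {}
    for name, seq in usable.items():
        track, path, _ = infer_scaffold(seq, [r[name] for r in refs_a], [r[name] for r in refs_b], params, emissions, s)
        tracks.append(track)
        paths[name] = path
    bases = {lab: 0 for lab in ANCESTRY_STATES}
    for track in tracks:
        for st, en, lab in track.intervals:
            bases[lab] += en - st
    summary = RunSummary(
        hybrid=hybrid_name,
        proportion=admixture_proportion(tracks),
        bases=bases,
        s=s,
        params={
            "g": params.g, "r": params.r, "p": params.p, "N": params.N,
            "w": params.w, "skip_threshold": params.skip_threshold,
            "a": params.a, "b": params.b,
            "pi_A": params.diversity.pi_A, "pi_B": params.diversity.pi_B,
            "pi_AB": params.diversity.pi_AB,
            "emission_mode": emissions.mode, "emission_shrinks": emissions.shrink_count,
        },
    )
    return tracks, summary, paths


@dataclass
class RunConfig:
    """File-level configuration for a multi-hybrid run (the CLI's main path)."""

    hybrids: list[Path]
    pop_a: list[Path]
    pop_b: list[Path]
    out_dir: Path
    generations: float
    pop_size: float
    outgroup: Path | None = None
    admix_prop: float | None = None
    fhat_refs: tuple[int, int] = (0, 1)
    window: int | None = None
    skip_threshold: float = 0.25
    recomb_rate: float = 1e-8
    min_scaffold_len: int = 500_000
    emission_mode: str = "analytic"
    processes: int = 1
    haploid_scaffolds: list[str] | None = None


def run(config: RunConfig) -> list[RunSummary]:
    """Run the full pipeline: estimate parameters, score, decode, write output.

    For each hybrid, writes ``<name>.ancestry.bed`` (BED3+1 with labels
    AA/AB/BB; A is always the lower-diversity reference population) and
    ``<name>.summary.json`` under ``config.out_dir``.
    """
    if config.haploid_scaffolds:
        raise NotImplementedError(
            "the haploid-scaffold (X/Z chromosome) transition adjustment is not implemented"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def load(path: Path) -> Mapping[str, PseudoHaploidSeq]:
        return seqio.filter_scaffolds(seqio.read_fasta(path), config.min_scaffold_len)

    refs_a = [load(p) for p in config.pop_a]
    refs_b = [load(p) for p in config.pop_b]
    pi_a = popstats.population_pi(refs_a) if len(refs_a) > 1 else None
    pi_b = popstats.population_pi(refs_b) if len(refs_b) > 1 else None
    if pi_a is None or pi_b is None:
        raise ValueError("need >= 2 individuals per population to estimate diversity")
    pi_ab = popstats.cross_population_pi(refs_a, refs_b)
    div, swapped = DiversityEstimates.designate(pi_a, pi_b, pi_ab)
    if swapped:
        logger.warning(
            "population A has higher diversity than population B; relabeling so "
            "that A is the lower-diversity population (AA = homozygous for the "
            "second panel's ancestry)"
        )
        refs_a, refs_b = refs_b, refs_a

    outgroup = load(config.outgroup) if config.outgroup else None
    jobs = [
        (Path(hy_path), config, div, refs_a, refs_b, outgroup) for hy_path in config.hybrids
    ]
    if config.processes > 1 and len(jobs) > 1:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=config.processes) as pool:
            summaries = list(pool.map(_run_one_hybrid, jobs))
    else:
        summaries = [_run_one_hybrid(job) for job in jobs]
    return summaries


def _run_one_hybrid(job) -> RunSummary:
    """Process one hybrid FASTA end-to-end (picklable worker)."""
    hy_path, config, div, refs_a, refs_b, outgroup = job
    name = Path(hy_path).stem
    hybrid = seqio.filter_scaffolds(seqio.read_fasta(hy_path), config.min_scaffold_len)
    if config.admix_prop is not None:
        p = max(config.admix_prop, popstats.P_FLOOR)
    else:
        if outgroup is None:
            raise ValueError("need an outgroup (or --admix-prop) to estimate p via f-hat")
        i, j = config.fhat_refs
        fh = popstats.f_hat(refs_b[0], hybrid, refs_a[i], refs_a[j], outgroup)
        p = fh.p_used
        logger.info("%s: f-hat = %.4f (p_used = %.4f)", name, fh.f_hat, p)
    params = ModelParams(
        g=config.generations, p=p, N=config.pop_size,
        a=len(refs_a), b=len(refs_b), diversity=div,
        w=config.window, r=config.recomb_rate, skip_threshold=config.skip_threshold,
    )
    if params.w is None:
        rec = recommend_window_size(params)
        logger.info("%s: recommended window size %d bp", name, rec.w)
        params = params.with_window(rec.w)
    emissions = build_emissions(params, mode=config.emission_mode)
    tracks, summary, _ = run_hybrid(hybrid, refs_a, refs_b, params, hybrid_name=name, emissions=emissions)
    rows = [row for tr in tracks for row in tr.bed_rows()]
    out_dir = Path(config.out_dir)
    seqio.write_bed(rows, out_dir / f"{name}.ancestry.bed")
    (out_dir / f"{name}.summary.json").write_text(summary.to_json() + "\n")
    return summary
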