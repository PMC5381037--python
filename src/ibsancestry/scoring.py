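"""IBS-tract extraction and per-window score computation.

The per-window score compares mean identity-by-state (IBS) tract lengths
between the hybrid and each reference panel:

    x = ln( (1/(a*w)) * sum_i mean_tract(hybrid, A_i) )
      - ln( (1/(b*w)) * sum_i mean_tract(hybrid, B_i) )

where a and b are the panel sizes and w the window size. Mean tract length
shrinks as divergence grows, so x is large when the window looks like
population A and negative when it looks like population B.

N handling: a position where either base is N is non-informative — it
neither extends nor terminates a tract. Tracts are maximal runs of matching
informative positions, delimited by mismatching informative positions or the
window edges; a zero-mismatch comparison yields a single tract spanning all
informative matches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import GenomeWindow, PseudoHaploidSeq, _N, tile_windows

logger = logging.getLogger(__name__)

__all__ = ["WindowScore", "ibs_tracts", "window_score", "score_scaffold"]


@dataclass(frozen=True)
class WindowScore:
    """Score for one genomic window; ``x is None`` marks a skipped window."""

    window: GenomeWindow
    x: float | None
    n_vs_a: int = 0
    n_vs_b: int = 0

    @property
    def is_skip(self) -> bool:
        return self.x is None


def _tracts_from_flags(informative: np.ndarray, mismatch: np.ndarray) -> np.ndarray:
    """Tract lengths given boolean site flags over a window slice."""
    k = int(informative.sum())
    if k == 0:
        return np.empty(0, dtype=np.int64)
    # positions of mismatches within the informative subsequence
    mm_idx = np.flatnonzero(mismatch[informative])
    segments = np.diff(np.concatenate(([-1], mm_idx, [k]))) - 1
    return segments[segments > 0]


def ibs_tracts(s1: PseudoHaploidSeq, s2: PseudoHaploidSeq, start: int, end: int) -> np.ndarray:
    """Lengths of maximal IBS tracts between two sequences over [start, end)."""
    if not (0 <= start < end <= min(s1.length, s2.length)):
        raise ValueError(f"window [{start}, {end}) outside both sequences")
    b1 = s1.bases[start:end]
    b2 = s2.bases[start:end]
    informative = (b1 != _N) & (b2 != _N)
    mismatch = informative & (b1 != b2)
    return _tracts_from_flags(informative, mismatch)


def window_score(
    hybrid: PseudoHaploidSeq,
    refs_a: Sequence[PseudoHaploidSeq],
    refs_b: Sequence[PseudoHaploidSeq],
    window: GenomeWindow,
    skip_threshold: float = 0.25,
) -> WindowScore:
    """Score one window, or mark it skipped.

    A window is skipped when its hybrid N-fraction exceeds ``skip_threshold``
    or when every individual in either panel yields no informative tract.
    Individuals with an empty tract list are excluded from their panel's
    average (with a log message) rather than failing the window.
    """
    if not refs_a or not refs_b:
        raise ValueError("both reference panels need at least one individual")
    if window.n_fraction > skip_threshold:
        return WindowScore(window=window, x=None)
    w = window.size

    sums = []
    counts = []
    for panel in (refs_a, refs_b):
        total_mean = 0.0
        included = 0
        n_tracts = 0
        for ref in panel:
            tracts = ibs_tracts(hybrid, ref, window.start, window.end)
            if tracts.size == 0:
                logger.debug(
                    "window %s:%d-%d: reference %s has no informative tracts; excluded",
                    window.scaffold, window.start, window.end, ref.name,
                )
                continue
            total_mean += float(tracts.mean())
            included += 1
            n_tracts += int(tracts.size)
        sums.append((total_mean, included))
        counts.append(n_tracts)

    (sum_a, a_inc), (sum_b, b_inc) = sums
    if a_inc == 0 or b_inc == 0:
        logger.warning(
            "window %s:%d-%d: an entire reference panel was excluded; skipping",
            window.scaffold, window.start, window.end,
        )
        return WindowScore(window=window, x=None, n_vs_a=counts[0], n_vs_b=counts[1])
    x = math.log(sum_a / (a_inc * w)) - math.log(sum_b / (b_inc * w))
    return WindowScore(window=window, x=x, n_vs_a=counts[0], n_vs_b=counts[1])


def score_scaffold(
    hybrid: PseudoHaploidSeq,
    refs_a: Sequence[PseudoHaploidSeq],
    refs_b: Sequence[PseudoHaploidSeq],
    w: int,
    skip_threshold: float = 0.25,
) -> tuple[list[WindowScore], float]:
    """Score every tiled window of a scaffold.

    Returns the ordered window scores and ``s``, the fraction of skipped
    windows on this scaffold.
    """
    windows = tile_windows(hybrid, w)
    if not windows:
        raise ValueError(
            f"scaffold {hybrid.name} ({hybrid.length} bp) is shorter than one window ({w} bp)"
        )
    for ref in list(refs_a) + list(refs_b):
        if ref.length < windows[-1].end:
            raise ValueError(f"reference {ref.name} does not cover scaffold {hybrid.name}")
    scores = [window_score(hybrid, refs_a, refs_b, win, skip_threshold) for win in windows]
    s = sum(sc.is_skip for sc in scores) / len(scores)
    return scores, s
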