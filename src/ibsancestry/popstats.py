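"""Population-level parameter estimation from pseudo-haploid sequences.

Two kinds of external model parameters are estimated here:

* nucleotide diversity pi — the per-compared-site mismatch rate between two
  sequences, averaged within a population or across two populations; and
* the f-hat admixture-proportion statistic — a ratio of two signed
  ABBA−BABA site-pattern sums, following the standard four-taxon convention
  applied to single pseudo-haploid bases.

Per-scaffold values are combined by pooling mismatch and comparable-site
counts (length weighting), never by averaging rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .seqio import PseudoHaploidSeq, _N

__all__ = [
    "DiversityEstimates",
    "FHatResult",
    "pairwise_pi",
    "population_pi",
    "cross_population_pi",
    "f_hat",
]

#: an individual's genome: a single sequence or a mapping scaffold -> sequence
Individual = Union[PseudoHaploidSeq, Mapping[str, PseudoHaploidSeq]]

P_FLOOR = 0.001


@dataclass(frozen=True)
class DiversityEstimates:
    """Within- and between-population nucleotide diversity.

    By convention population A is the lower-diversity population; the
    constructor relabels (swaps pi_A and pi_B) if needed.
    """

    pi_A: float
    pi_B: float
    pi_AB: float

    def __post_init__(self):
        for name in ("pi_A", "pi_B", "pi_AB"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pi_A > self.pi_B:
            a, b = self.pi_A, self.pi_B
            object.__setattr__(self, "pi_A", b)
            object.__setattr__(self, "pi_B", a)

    @property
    def swapped(self) -> bool:
        # reconstructable only by the caller who knows the input order; kept
        # as a helper for designate()
        return False

    @classmethod
    def designate(cls, pi_1: float, pi_2: float, pi_12: float) -> tuple["DiversityEstimates", bool]:
        """Build estimates from two populations in user order.

        Returns the estimates plus a flag that is True when the *second*
        population was designated A (i.e. the labels were swapped).
        """
        return cls(pi_A=pi_1, pi_B=pi_2, pi_AB=pi_12), pi_1 > pi_2


@dataclass(frozen=True)
class FHatResult:
    """f-hat admixture-proportion estimate.

    ``s_num``/``s_den`` are the signed ABBA−BABA sums for the hybrid and the
    two-introgressor configurations; ``p_used`` floors the ratio at 0.001 so
    the ancestry model can still detect unexpected introgression.
    """

    s_num: float
    s_den: float

    @property
    def f_hat(self) -> float:
        return self.s_num / self.s_den

    @property
    def p_used(self) -> float:
        return max(self.f_hat, P_FLOOR)


def _as_scaffold_map(ind: Individual) -> Mapping[str, PseudoHaploidSeq]:
    if isinstance(ind, PseudoHaploidSeq):
        return {ind.name: ind}
    return ind


def _mismatch_counts(s1: PseudoHaploidSeq, s2: PseudoHaploidSeq) -> tuple[int, int]:
    if s1.length != s2.length:
        raise ValueError(f"sequence lengths differ: {s1.length} != {s2.length}")
    informative = (s1.bases != _N) & (s2.bases != _N)
    compared = int(informative.sum())
    mismatches = int((informative & (s1.bases != s2.bases)).sum())
    return mismatches, compared


def pairwise_pi(seq1: PseudoHaploidSeq, seq2: PseudoHaploidSeq) -> float:
    """Per-site mismatch rate over positions where both bases are in {A,C,G,T}."""
    mism, comp = _mismatch_counts(seq1, seq2)
    if comp == 0:
        raise ValueError("no comparable (both non-N) positions")
    return mism / comp


def _pooled_pair_pi(ind1: Individual, ind2: Individual) -> tuple[int, int]:
    if isinstance(ind1, PseudoHaploidSeq) and isinstance(ind2, PseudoHaploidSeq):
        return _mismatch_counts(ind1, ind2)
    m1, m2 = _as_scaffold_map(ind1), _as_scaffold_map(ind2)
    shared = [k for k in m1 if k in m2]
    if not shared:
        raise ValueError("individuals share no scaffolds")
    mism = comp = 0
    for k in shared:
        a, b = _mismatch_counts(m1[k], m2[k])
        mism += a
        comp += b
    return mism, comp


def population_pi(seqs: Sequence[Individual]) -> float:
    """Mean pairwise mismatch rate over all unordered within-population pairs."""
    if len(seqs) < 2:
        raise ValueError("within-population pi requires at least 2 individuals")
    mism = comp = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = _pooled_pair_pi(seqs[i], seqs[j])
            mism += a
            comp += b
    if comp == 0:
        raise ValueError("no comparable positions in any pair")
    return mism / comp


def cross_population_pi(pop_a: Sequence[Individual], pop_b: Sequence[Individual]) -> float:
    """Mean pairwise mismatch rate over all cross-population pairs."""
    if not pop_a or not pop_b:
        raise ValueError("both populations need at least one individual")
    mism = comp = 0
    for x in pop_a:
        for y in pop_b:
            a, b = _pooled_pair_pi(x, y)
            mism += a
            comp += b
    if comp == 0:
        raise ValueError("no comparable positions in any pair")
    return mism / comp


def _abba_baba_counts(
    p1: PseudoHaploidSeq, p2: PseudoHaploidSeq, p3: PseudoHaploidSeq, out: PseudoHaploidSeq
) -> tuple[int, int]:
    """Count ABBA and BABA biallelic site patterns for (P1, P2, P3, O).

    ABBA: P2 and P3 share the allele not carried by P1 and O.
    BABA: P1 and P3 share it. Sites with any N, with more than two alleles,
    or where the outgroup disagrees with the major pattern are skipped
    (implicitly: the two patterns above are the only ones counted).
    """
    arrays = [p1.bases, p2.bases, p3.bases, out.bases]
    n = min(a.size for a in arrays)
    a, b, c, d = (arr[:n] for arr in arrays)
    informative = (a != _N) & (b != _N) & (c != _N) & (d != _N)
    abba = informative & (a == d) & (b == c) & (a != b)
    baba = informative & (b == d) & (a == c) & (a != b)
    return int(abba.sum()), int(baba.sum())


def f_hat(
    p1_unadmixed_b: Individual,
    p2_hybrid: Individual,
    p3a_a: Individual,
    p3b_a: Individual,
    outgroup: Individual,
) -> FHatResult:
    """Estimate the fraction of the hybrid genome derived from population A.

    With S(P1,P2,P3,O) the signed ABBA−BABA sum, returns
    ``S(P1, hybrid, P3a, O) / S(P1, P3b, P3a, O)``: the hybrid's excess
    allele sharing with the introgressor, normalized by that of a second
    introgressor individual. Counts are pooled over shared scaffolds.
    """
    inputs = (p1_unadmixed_b, p2_hybrid, p3a_a, p3b_a, outgroup)
    if all(isinstance(x, PseudoHaploidSeq) for x in inputs):
        # bare sequences: align positionally regardless of record names
        tuples = [inputs]
    else:
        maps = [_as_scaffold_map(x) for x in inputs]
        shared = [k for k in maps[0] if all(k in m for m in maps[1:])]
        if not shared:
            raise ValueError("the five individuals share no scaffolds")
        tuples = [tuple(m[k] for m in maps) for k in shared]
    s_num = s_den = 0
    for p1, p2, p3a, p3b, o in tuples:
        ab, ba = _abba_baba_counts(p1, p2, p3a, o)
        s_num += ab - ba
        ab, ba = _abba_baba_counts(p1, p3b, p3a, o)
        s_den += ab - ba
    if s_den == 0:
        raise ValueError(
            "f-hat denominator is zero (no informative ABBA/BABA sites between "
            "the two population-A individuals); supply the admixture "
            "proportion p directly"
        )
    return FHatResult(s_num=float(s_num), s_den=float(s_den))
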