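"""Coalescent simulation backend (msprime) with genealogy-derived truth.

Implements a four-population demography shaped like the polar/brown-bear
system: an island hybrid population founded 50/50 from the two species ~12
kya (1057 generations at 11.35 y/generation), a polar-brown split at 411
kya, a distant outgroup (black bear), and — in the "migration" variant —
continuous replacement of the island population by mainland brown bears at
0.001 per generation from admixture until the present.

Effective sizes derive from per-site diversities theta = 4*N*mu with
mu = 1.825728e-8: theta_brown = 0.0017 (N0 = 23278), theta_polar = 4e-4
(0.2353*N0), theta_black = 0.0021 (1.2353*N0). Recombination is flat at
1 cM/Mb. Mutations use an HKY model with a 4:1 transition:transversion
ratio (kappa = 8).

Truth for each hybrid haplotype follows the TMRCA rule of
:func:`ibsancestry.simtruth.truth_from_trees`, evaluated directly on the
tree sequence for speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .seqio import PseudoHaploidSeq
from .simtruth import TruthTrack, _CODE_TO_ASCII, _merge_labeled, _pseudo_haploid_codes

__all__ = [
    "MU", "GEN_TIME", "N0", "T_ADMIX", "T_SPLIT", "T_OUTGROUP",
    "bear_demography", "simulate_bear_replicate", "BearReplicate",
]

MU = 1.825728e-8  # per site per generation
GEN_TIME = 11.35  # years
RECOMB = 1e-8  # 1 cM/Mb
N0 = 0.0017 / (4.0 * MU)  # brown-bear effective size, ~23278
POLAR_RATIO = 0.235294117647  # theta_polar / theta_brown
OUTGROUP_RATIO = 1.23529411765  # theta_black / theta_brown
T_ADMIX = 12_000.0 / GEN_TIME  # ~1057 generations
T_SPLIT = 411_000.0 / GEN_TIME  # ~36211 generations
T_OUTGROUP = 8.89445099767 * 4.0 * N0  # outgroup join, in generations
MIGRATION_RATE = 0.001  # per generation, brown -> island (forwards in time)

_ASCII_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def bear_demography(migration: bool) -> msprime.Demography:
    """Four-population demography; ``migration`` enables post-admixture gene flow."""
    dem = msprime.Demography()
    dem.add_population(name="polar", initial_size=POLAR_RATIO * N0)
    dem.add_population(name="island", initial_size=N0)
    dem.add_population(name="brown", initial_size=N0)
    dem.add_population(name="outgroup", initial_size=OUTGROUP_RATIO * N0)
    if migration:
        # forwards in time: brown migrants replace island individuals, so
        # lineages move island -> brown backwards in time
        dem.set_migration_rate(source="island", dest="brown", rate=MIGRATION_RATE)
        dem.add_migration_rate_change(time=T_ADMIX, source="island", dest="brown", rate=0.0)
    # admixture pulse: island founded 50% polar, 50% brown
    dem.add_mass_migration(time=T_ADMIX, source="island", dest="brown", proportion=0.5)
    dem.add_mass_migration(time=T_ADMIX, source="island", dest="polar", proportion=1.0)
    dem.add_mass_migration(time=T_SPLIT, source="polar", dest="brown", proportion=1.0)
    dem.add_mass_migration(time=T_OUTGROUP, source="brown", dest="outgroup", proportion=1.0)
    dem.sort_events()
    return dem


@dataclass
class BearReplicate:
    """One simulated replicate: pseudo-haploid genomes and per-hybrid truth."""

    hybrids: list[dict[str, PseudoHaploidSeq]]
    polar: list[dict[str, PseudoHaploidSeq]]
    brown: list[dict[str, PseudoHaploidSeq]]
    outgroup: dict[str, PseudoHaploidSeq]
    truths: list[dict[str, TruthTrack]]


def _tree_sequence_codes(ts, rng: np.random.Generator) -> np.ndarray:
    """Per-sample nucleotide codes (n_samples, L): random monomorphic
    background overwritten at variant sites."""
    L = int(ts.sequence_length)
    n = ts.num_samples
    base = rng.integers(0, 4, size=L, dtype=np.uint8)
    seqs = np.broadcast_to(base, (n, L)).copy()
    for var in ts.variants():
        pos = int(var.site.position)
        allele_codes = np.array(
            [_ASCII_CODE.get(al, 0) if al else 0 for al in var.alleles], dtype=np.uint8
        )
        seqs[:, pos] = allele_codes[var.genotypes]
    return seqs


def _truth_for_tree_sequence(ts, hybrid_nodes, polar_nodes, brown_nodes) -> list[TruthTrack]:
    """TMRCA-rule truth per hybrid haplotype pair, from tskit trees."""
    n_hyb = len(hybrid_nodes) // 2
    per_hyb_intervals: list[list] = [[] for _ in range(n_hyb)]
    polar = list(polar_nodes)
    brown = list(brown_nodes)
    for tree in ts.trees():
        start, end = int(tree.interval.left), int(tree.interval.right)
        if end <= start:
            continue
        origins = []
        for u in hybrid_nodes:
            t_a = ts.node(tree.mrca(u, *polar)).time
            t_b = ts.node(tree.mrca(u, *brown)).time
            if t_a == t_b:
                origins.append(None)
            elif t_a < t_b and t_a < T_SPLIT:
                origins.append("A")
            else:
                origins.append("B")
        for h in range(n_hyb):
            o1, o2 = origins[2 * h], origins[2 * h + 1]
            if o1 is None or o2 is None:
                lab = "none"
            elif o1 == o2:
                lab = o1 * 2
            else:
                lab = "AB"
            per_hyb_intervals[h].append((start, end, lab))
    return [TruthTrack(intervals=_merge_labeled(iv)) for iv in per_hyb_intervals]


def simulate_bear_replicate(
    model: str = "migration",
    seed: int = 1,
    n_chrom: int = 10,
    L: int = 1_000_000,
    n_refs: int = 5,
    n_hybrids: int = 5,
) -> BearReplicate:
    """Simulate one replicate of the validation demography.

    ``model`` is "migration" or "single_pulse". Returns pseudo-haploid
    genomes for ``n_hybrids`` island hybrids, ``n_refs`` polar and brown
    references each, one outgroup individual, and genealogy-derived truth
    tracks for every hybrid chromosome.
    """
    if model not in ("migration", "single_pulse"):
        raise ValueError(f"unknown model {model!r}")
    dem = bear_demography(migration=(model == "migration"))
    rng = np.random.default_rng(seed)
    samples = [
        msprime.SampleSet(n_refs, population="polar"),
        msprime.SampleSet(n_refs, population="brown"),
        msprime.SampleSet(n_hybrids, population="island"),
        msprime.SampleSet(1, population="outgroup"),
    ]
    polar_nodes = list(range(0, 2 * n_refs))
    brown_nodes = list(range(2 * n_refs, 4 * n_refs))
    hybrid_nodes = list(range(4 * n_refs, 4 * n_refs + 2 * n_hybrids))
    out_nodes = [4 * n_refs + 2 * n_hybrids, 4 * n_refs + 2 * n_hybrids + 1]

    hybrids: list[dict] = [dict() for _ in range(n_hybrids)]
    polar: list[dict] = [dict() for _ in range(n_refs)]
    brown: list[dict] = [dict() for _ in range(n_refs)]
    outgroup: dict = {}
    truths: list[dict] = [dict() for _ in range(n_hybrids)]

    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        anc_seed = int(rng.integers(1, 2**31 - 1))
        mut_seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=samples, demography=dem, sequence_length=L,
            recombination_rate=RECOMB, random_seed=anc_seed,
        )
        ts = msprime.sim_mutations(ts, rate=MU, model=msprime.HKY(kappa=8.0), random_seed=mut_seed)
        seqs = _tree_sequence_codes(ts, rng)

        def _individual(name: str, node_pair) -> PseudoHaploidSeq:
            codes = _pseudo_haploid_codes(seqs[node_pair[0]], seqs[node_pair[1]], rng)
            return PseudoHaploidSeq(name=chrom, bases=_CODE_TO_ASCII[codes])

        for i in range(n_refs):
            polar[i][chrom] = _individual(f"P{i}", polar_nodes[2 * i : 2 * i + 2])
            brown[i][chrom] = _individual(f"B{i}", brown_nodes[2 * i : 2 * i + 2])
        for h in range(n_hybrids):
            hybrids[h][chrom] = _individual(f"H{h}", hybrid_nodes[2 * h : 2 * h + 2])
        outgroup[chrom] = _individual("OUT", out_nodes)

        for h, truth in enumerate(_truth_for_tree_sequence(ts, hybrid_nodes, polar_nodes, brown_nodes)):
            truths[h][chrom] = truth
    return BearReplicate(hybrids=hybrids, polar=polar, brown=brown, outgroup=outgroup, truths=truths)
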