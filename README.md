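# ibsancestry

Local ancestry inference for hybrid diploid genomes from **low-coverage,
pseudo-haploid** sequence data — no variant calling, no phasing, no
reference haplotype panels.

## The problem

When two recently diverged populations or species hybridize (the motivating
system is polar-bear introgression into brown bears; archaic introgression
into modern humans is analogous), each segment of an admixed individual's
genome is homozygous for ancestry from population A, heterozygous, or
homozygous for population B. Standard local-ancestry tools require accurate
genotype calls and phased reference haplotypes, which low-coverage shotgun
data from non-model or ancient samples cannot provide. `ibsancestry`
instead works on *pseudo-haploid* FASTA sequences — one base per site,
randomly drawn from one of the two homologues — and lets whole genomic
windows vote on their ancestry.

## The method

For each non-overlapping window of width *w*, the hybrid is compared with
*a* reference individuals from population A and *b* from population B. With
*IBS<sub>i,j</sub>* the length of the *j*-th identity-by-state tract against
reference *i* (maximal runs of matching bases; sites with N neither extend
nor break a tract), the window score is

```
x = ln( (1/(a·w)) Σ_i  mean_j IBS_{i,j}  over panel A )
  − ln( (1/(b·w)) Σ_i  mean_j IBS_{i,j}  over panel B )
```

Mean IBS tract length is ≈ 1/divergence, so `x` is strongly positive in
windows of homozygous A ancestry, near an intermediate value for
heterozygous windows, and negative for homozygous B ancestry.

The score sequence is decoded by a six-state hidden Markov model
(AA, AB, BB plus three *skip* states that absorb windows with too much
missing data while remembering the flanking ancestry):

* **Transitions** follow recombination since admixture: with *g* generations
  and per-site rate *r* (1 cM/Mb default), each homologue switches ancestry
  within one window step with probability `R = 1 − (1 − g·r)^w`, landing in
  population A with probability *p* (the admixture proportion). Genetic
  drift lets one ancestral recombination event be inherited on *both*
  homologues; that probability per site,
  `z = r·(g − (2N−1)·(1 − (1−1/(2N))^g))`, is the closed form of the
  Wright–Fisher second-moment recursion and enters e.g.
  `P(AA→BB) = R²(1−p)² + Z(1−p)` with `Z = 1 − (1−z)^w`.
* **Emissions** are normal distributions of `x` per ancestry state whose
  means and SDs are derived from the nucleotide diversities π_A, π_B, π_AB
  (or calibrated by Monte Carlo against the package's own generative
  model). Windows whose N-fraction exceeds the skip threshold emit a SKIP
  sentinel that only skip states accept.
* **Decoding** is Viterbi; the per-window path is merged into BED intervals.

Supporting estimators: pairwise/population nucleotide diversity (π), the
ABBA–BABA **f̂** statistic for the admixture proportion *p* (floored at
0.001), and a window-size recommender that picks the smallest *w* whose
emission distributions overlap by ≤ 0.5 (overlap = ∫ min(f_i, f_j)).

The population with **lower diversity is always labeled A** (introgressor
convention in the bear system: A = polar bear).

## Worked example

```bash
python examples/01_score_and_decode.py
```

builds a 500 kb synthetic hybrid scaffold with known ancestry and prints:

```
inferred ancestry tracts (scaffold, start, end, state):
  chr1  0       280000  AB
  chr1  280000  290000  BB
  chr1  290000  340000  AB
  chr1  340000  450000  AA
  chr1  450000  500000  AB

admixture proportion (2*AA + AB)/(2*total): 0.600
true simulated A-ancestry fraction:          0.589
```

Each line is an inferred ancestry tract; the admixture proportion counts
homologous chromosomes carrying A ancestry
(`(2·AA + AB) / (2·labeled bases)`) and matches the simulated truth. The
other examples cover parameter estimation (`02`), window-size choice
(`03`), and validation against mosaic (`04`) and coalescent (`05`)
simulations with known truth.

A thin CLI mirrors the library:

```bash
ibsancestry run --hybrid hyb.fa --popA a1.fa --popA a2.fa --popB b1.fa --popB b2.fa \
    --outgroup out.fa --generations 1000 --pop-size 3000 -o outdir
ibsancestry simulate -o simdir --n-hybrids 2 --n-chrom 5
ibsancestry evaluate --calls outdir/hyb.ancestry.bed --truth simdir/hybrid1.truth.bed --window 10000
```

`run` writes `<hybrid>.ancestry.bed` (BED3+1, labels AA/AB/BB) and
`<hybrid>.summary.json` per hybrid.

## Scope notes

Read mapping, variant calling and phasing are upstream of this package;
inputs are pseudo-haploid FASTAs. The X/Z-chromosome transition variant is
reserved in the interface but not implemented. See `docs/methods.md` for
the model's assumptions, parameter defaults, and known limitations.
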