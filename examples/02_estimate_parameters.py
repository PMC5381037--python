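"""Estimate nucleotide diversity and the f-hat admixture proportion.

Simulates panels with known diversity targets and a hybrid with known
ancestry fraction, then estimates pi within/between populations (pooled
mismatch counts over all pairs) and f-hat (the ABBA-BABA ratio). Realized
pi should sit within a few percent of the targets; f-hat should recover the
simulated ancestry fraction.
"""

import numpy as np

from ibsancestry import popstats, simtruth

cfg = simtruth.SimConfig(L=1_000_000, n_chrom=5, n_hybrids=1, p_sim=0.25, seed=42)
mosaics = simtruth.simulate_mosaic(cfg)
seqset = simtruth.materialize_sequences(cfg, mosaics)

pi_a = popstats.population_pi(seqset.panel_a)
pi_b = popstats.population_pi(seqset.panel_b)
pi_ab = popstats.cross_population_pi(seqset.panel_a, seqset.panel_b)
print(f"pi_A  = {pi_a:.6f} (target {cfg.pi_a})")
print(f"pi_B  = {pi_b:.6f} (target {cfg.pi_b})")
print(f"pi_AB = {pi_ab:.6f} (target {cfg.pi_ab})")

fh = popstats.f_hat(
    seqset.panel_b[0], seqset.hybrids[0], seqset.panel_a[0], seqset.panel_a[1], seqset.outgroup
)
truth = np.mean([(m.hap1.a_fraction() + m.hap2.a_fraction()) / 2 for m in mosaics[0]])
print(f"\nf-hat = {fh.f_hat:.4f} (s_num={fh.s_num:.0f}, s_den={fh.s_den:.0f})")
print(f"true A-ancestry fraction = {truth:.4f}")
print("f-hat is the model's admixture-proportion estimate p (floored at 0.001)")
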