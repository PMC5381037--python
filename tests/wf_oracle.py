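"""Forward Wright-Fisher Monte Carlo oracle for the resampling probability z.

About 2N*r recombination events arise per generation per site, each on a
single chromosome (frequency 1/(2N)); the probability that a present-day
individual carries the same event on both homologues is E[(c/2N)^2] summed
over event cohorts. We simulate single-event count trajectories forward
under binomial resampling (the exact marginal dynamics of one allele in a
Wright-Fisher population of 2N chromosomes) and accumulate the squared
frequency after every elapsed-drift duration 0..g-1, so one trajectory set
serves every cohort.
"""

from __future__ import annotations

import numpy as np


def wf_z_monte_carlo(
    N: int, g: int, r: float, n_reps: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Return (z estimate, Monte Carlo standard error)."""
    two_n = 2 * N
    counts = np.ones(n_reps, dtype=np.int64)
    per_traj = np.empty((g, n_reps))
    per_traj[0] = (counts / two_n) ** 2  # zero generations of drift
    for k in range(1, g):
        counts = rng.binomial(two_n, counts / two_n)
        per_traj[k] = (counts / two_n) ** 2
    stat = per_traj.sum(axis=0)  # per-trajectory sum over cohort ages
    z_hat = 2 * N * r * float(stat.mean())
    se = 2 * N * r * float(stat.std(ddof=1)) / np.sqrt(n_reps)
    return z_hat, se
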