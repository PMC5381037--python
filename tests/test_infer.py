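import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibsancestry import infer, model, seqio, simtruth
from ibsancestry.infer import (
    AncestryTrack,
    RunConfig,
    admixture_proportion,
    decode,
    path_log_probability,
    path_to_track,
)
from ibsancestry.model import STATES, EmissionSpec, ModelParams, build_emissions, build_transitions
from ibsancestry.scoring import WindowScore
from ibsancestry.seqio import GenomeWindow


def _scores(xs, w=10, scaffold="s"):
    """Window scores from a list of floats (None = SKIP)."""
    out = []
    for k, x in enumerate(xs):
        win = GenomeWindow(scaffold=scaffold, start=k * w, end=(k + 1) * w, n_fraction=0.0 if x is not None else 1.0)
        out.append(WindowScore(window=win, x=x))
    return out


def _setup(bear_div, p=0.5, n_windows=6, s=0.0, g=1000):
    params = ModelParams(g=g, p=p, N=3000, a=5, b=5, diversity=bear_div, w=10_000)
    tm = build_transitions(params, n_windows=n_windows, s=s)
    em = build_emissions(params, mode="analytic")
    return params, tm, em


def brute_force_viterbi(scores, tm, em):
    """Exhaustive path search, scoring paths with the shared log-probability
    contract; first (lexicographically smallest) maximizer wins."""
    n = len(scores)
    best_path, best_lp = None, -math.inf
    for path in itertools.product(range(6), repeat=n):
        lp = path_log_probability(path, scores, tm, em)
        if lp > best_lp:
            best_path, best_lp = path, lp
    return tuple(STATES[i] for i in best_path)


class TestDecode:
    def test_single_window_at_aa_mean(self, bear_div):
        params, tm, em = _setup(bear_div, p=0.5, n_windows=1)
        path = decode(_scores([float(em.mu[0])]), tm, em)
        assert path.labels == ("AA",)

    def test_matches_brute_force_on_random_instances(self, bear_div, rng):
        params, _, em = _setup(bear_div)
        for trial in range(40):
            n = int(rng.integers(2, 6))
            s = float(rng.uniform(0.0, 0.4))
            tm = build_transitions(params, n_windows=n, s=s)
            xs = [
                None if rng.random() < 0.25 and k > 0 else float(rng.normal(rng.choice(em.mu), 0.5))
                for k in range(n)
            ]
            scores = _scores(xs)
            if all(x is None for x in xs):
                continue
            assert decode(scores, tm, em).states == brute_force_viterbi(scores, tm, em)

    def test_emission_dominates_weak_transitions(self, bear_div):
        params, tm, em = _setup(bear_div, n_windows=6)
        xs = [em.mu[0], em.mu[2], em.mu[0], em.mu[2], em.mu[0], em.mu[2]]
        path = decode(_scores([float(v) for v in xs]), tm, em)
        assert path.labels == ("AA", "BB", "AA", "BB", "AA", "BB")

    def test_g_zero_forbids_switching(self, bear_div):
        params, tm, em = _setup(bear_div, n_windows=6, g=0)
        xs = [em.mu[0], em.mu[2], em.mu[0], em.mu[2], em.mu[0], em.mu[2]]
        path = decode(_scores([float(v) for v in xs]), tm, em)
        assert len(set(path.labels)) == 1

    def test_skip_windows_inherit_flanking_state(self, bear_div):
        params, tm, em = _setup(bear_div, n_windows=5, s=0.2)
        scores = _scores([float(em.mu[0]), None, None, float(em.mu[0]), float(em.mu[0])])
        path = decode(scores, tm, em)
        assert path.labels == ("AA",) * 5
        assert path.imputed == (False, True, True, False, False)

    def test_leading_skip_window_decodable(self, bear_div):
        params, tm, em = _setup(bear_div, n_windows=3, s=0.2)
        scores = _scores([None, float(em.mu[2]), float(em.mu[2])])
        path = decode(scores, tm, em)
        assert path.labels == ("BB", "BB", "BB")
        assert path.imputed[0]

    def test_all_skip_errors(self, bear_div):
        params, tm, em = _setup(bear_div, n_windows=2, s=0.5)
        with pytest.raises(ValueError, match="skip"):
            decode(_scores([None, None]), tm, em)

    def test_adding_constant_never_decreases_aa_calls(self, bear_div, rng):
        params, _, em = _setup(bear_div)
        shift = float(em.mu[0] - em.mu[2])
        for _ in range(30):
            n = int(rng.integers(2, 10))
            tm = build_transitions(params, n_windows=n, s=0.0)
            xs = rng.normal(0.0, 1.0, size=n)
            base = decode(_scores([float(v) for v in xs]), tm, em).labels
            up = decode(_scores([float(v + shift) for v in xs]), tm, em).labels
            assert up.count("AA") >= base.count("AA")


class TestPathToTrack:
    def test_merges_same_label_windows(self):
        wins = [GenomeWindow("s", k * 10, (k + 1) * 10, 0.0) for k in range(3)]
        track = path_to_track(["AA", "AA", "AB"], wins)
        assert track.intervals == ((0, 20, "AA"), (20, 30, "AB"))

    def test_single_label_single_interval(self):
        wins = [GenomeWindow("s", k * 10, (k + 1) * 10, 0.0) for k in range(4)]
        track = path_to_track(["BB"] * 4, wins)
        assert track.intervals == ((0, 40, "BB"),)

    def test_empty_path(self):
        assert path_to_track([], []).intervals == ()


class TestAdmixtureProportion:
    def test_mixed_counts(self):
        track = AncestryTrack("s", ((0, 10, "AA"), (10, 20, "AB"), (20, 40, "BB")))
        # (2*10 + 10) / (2*40)
        assert admixture_proportion([track]) == pytest.approx(0.375)

    def test_all_bb_zero(self):
        assert admixture_proportion([AncestryTrack("s", ((0, 50, "BB"),))]) == 0.0

    def test_all_aa_one(self):
        assert admixture_proportion([AncestryTrack("s", ((0, 50, "AA"),))]) == 1.0

    def test_no_labeled_bases_errors(self):
        with pytest.raises(ValueError):
            admixture_proportion([AncestryTrack("s", ())])

    @given(
        counts=st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_direct_counting(self, counts):
        aa, ab, bb = counts
        intervals, pos = [], 0
        for n, lab in ((aa, "AA"), (ab, "AB"), (bb, "BB")):
            if n:
                intervals.append((pos, pos + n * 10, lab))
                pos += n * 10
        track = AncestryTrack("s", tuple(intervals))
        expected = (2 * aa + ab) / (2 * (aa + ab + bb))
        assert admixture_proportion([track]) == pytest.approx(expected)


@pytest.fixture(scope="module")
def small_genome(tmp_path_factory):
    """A small synthetic data set written as FASTA files for run() tests."""
    out = tmp_path_factory.mktemp("genome")
    cfg = simtruth.SimConfig(L=400_000, n_chrom=2, n_hybrids=2, p_sim=0.3, seed=99)
    mosaics = simtruth.simulate_mosaic(cfg)
    seqset = simtruth.materialize_sequences(cfg, mosaics)
    paths = {"hybrids": [], "a": [], "b": []}
    for h, hyb in enumerate(seqset.hybrids):
        p = out / f"hyb{h}.fa"
        seqio.write_fasta(hyb, p)
        paths["hybrids"].append(p)
    for i, ind in enumerate(seqset.panel_a):
        p = out / f"a{i}.fa"
        seqio.write_fasta(ind, p)
        paths["a"].append(p)
    for i, ind in enumerate(seqset.panel_b):
        p = out / f"b{i}.fa"
        seqio.write_fasta(ind, p)
        paths["b"].append(p)
    og = out / "outgroup.fa"
    seqio.write_fasta(seqset.outgroup, og)
    paths["outgroup"] = og
    paths["mosaics"] = mosaics
    return paths


class TestRun:
    def _config(self, paths, out_dir, **kw):
        defaults = dict(
            hybrids=paths["hybrids"], pop_a=paths["a"], pop_b=paths["b"],
            outgroup=paths["outgroup"], generations=1000, pop_size=3000,
            window=10_000, min_scaffold_len=100_000, out_dir=out_dir,
        )
        defaults.update(kw)
        return RunConfig(**defaults)

    def test_recovers_admixture_proportion(self, small_genome, tmp_path):
        summaries = infer.run(self._config(small_genome, tmp_path / "o"))
        mosaics = small_genome["mosaics"]
        for h, summ in enumerate(summaries):
            truth = np.mean(
                [(m.hap1.a_fraction() + m.hap2.a_fraction()) / 2 for m in mosaics[h]]
            )
            assert abs(summ.proportion - truth) < 0.08

    def test_reference_reused_as_hybrid_negative_control(self, small_genome, tmp_path):
        cfg = self._config(
            small_genome, tmp_path / "neg", hybrids=[small_genome["b"][4]], admix_prop=0.001
        )
        (summary,) = infer.run(cfg)
        assert summary.proportion <= 0.05

    def test_worker_count_does_not_change_output(self, small_genome, tmp_path):
        cfg1 = self._config(small_genome, tmp_path / "w1", processes=1)
        cfg2 = self._config(small_genome, tmp_path / "w2", processes=2)
        infer.run(cfg1)
        infer.run(cfg2)
        for hy in small_genome["hybrids"]:
            name = hy.stem
            b1 = (tmp_path / "w1" / f"{name}.ancestry.bed").read_bytes()
            b2 = (tmp_path / "w2" / f"{name}.ancestry.bed").read_bytes()
            assert b1 == b2
            s1 = json.loads((tmp_path / "w1" / f"{name}.summary.json").read_text())
            s2 = json.loads((tmp_path / "w2" / f"{name}.summary.json").read_text())
            assert s1 == s2

    def test_haploid_scaffold_flag_rejected(self, small_genome, tmp_path):
        cfg = self._config(small_genome, tmp_path / "x", haploid_scaffolds=["chr1"])
        with pytest.raises(NotImplementedError):
            infer.run(cfg)

    def test_summary_json_fields(self, small_genome, tmp_path):
        out = tmp_path / "fields"
        infer.run(self._config(small_genome, out))
        data = json.loads((out / "hyb0.summary.json").read_text())
        assert set(data) == {"hybrid", "admixture_proportion", "bases", "skip_fraction", "params"}
        assert set(data["bases"]) == {"AA", "AB", "BB"}
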