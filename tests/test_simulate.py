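"""Synthetic-study generator: determinism, composition, truth fidelity."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from exposig.classify import classify_records
from exposig.compare import cosine_similarity
from exposig.schemes import SBS96
from exposig.simulate import (
    SimulationConfig,
    SiteIndex,
    _Process,
    default_background_sbs96,
    default_exposure_id83,
    default_exposure_sbs96,
    simulate_clone,
    simulate_reference,
    simulate_study,
)


def _small_cfg(**kw):
    base = dict(seed=1, n_contigs=1, contig_length_bp=60_000,
                background_burden=200, exposure_burden=300)
    base.update(kw)
    return SimulationConfig(**base)


def _proc(sbs, burden, dbs_frac=0.0, ind_frac=0.0, name="p"):
    from exposig.simulate import (
        default_background_dbs78,
        default_background_id83,
    )

    return _Process(
        name, sbs, default_background_dbs78(), default_background_id83(),
        burden, dbs_frac, ind_frac,
    )


class TestReference:
    def test_gc_fraction_within_sampling_error(self):
        for gc in (0.5, 0.9):
            g = simulate_reference(_small_cfg(gc_fraction=gc, contig_length_bp=10_000))
            seq = g.contigs["chr1"]
            obs = (seq.count("G") + seq.count("C")) / len(seq)
            sd = np.sqrt(gc * (1 - gc) / len(seq))
            assert abs(obs - gc) < 3 * sd

    def test_same_seed_same_sequence(self):
        a = simulate_reference(_small_cfg())
        b = simulate_reference(_small_cfg())
        assert a.contigs == b.contigs

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            SimulationConfig(contig_length_bp=500)


@pytest.fixture(scope="module")
def genome():
    return simulate_reference(_small_cfg(contig_length_bp=100_000, seed=5))


class TestClone:
    def test_zero_burden_empty_clone(self, genome):
        rng = np.random.Generator(np.random.PCG64(1))
        recs, truth = simulate_clone(genome, [_proc(default_background_sbs96(), 0.0)], rng, "c")
        assert recs == [] and len(truth) == 0

    def test_one_hot_signature_constrains_truth_channels(self, genome):
        w = np.zeros(96)
        w[SBS96.index["A[C>A]A"]] = 1.0
        rng = np.random.Generator(np.random.PCG64(2))
        recs, truth = simulate_clone(genome, [_proc(w, 400)], rng, "c")
        assert len(recs) > 300
        assert set(truth.channel) == {"A[C>A]A"}

    def test_two_channel_mix_splits_binomially(self, genome):
        w = np.zeros(96)
        w[SBS96.index["A[C>A]A"]] = 0.5
        w[SBS96.index["T[T>G]T"]] = 0.5
        rng = np.random.Generator(np.random.PCG64(3))
        _, truth = simulate_clone(genome, [_proc(w, 2000)], rng, "c")
        n = len(truth)
        k = (truth.channel == "A[C>A]A").sum()
        assert abs(k - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_channel_without_sites_raises(self, genome):
        one_hot = np.zeros(83)
        one_hot[-1] = 1.0  # 5:Del:M:5 — the simulator indexes 1-bp indels only
        proc = _proc(default_background_sbs96(), 50, ind_frac=1.0)
        proc = _Process("p", proc.sbs, proc.dbs, one_hot, 50, 0.0, 1.0)
        rng = np.random.Generator(np.random.PCG64(4))
        with pytest.raises(ValueError, match="no matching site"):
            simulate_clone(genome, [proc], rng, "c")

    def test_high_burden_frequencies_match_signature(self, genome):
        """Empirical channel frequencies of a large clone track the
        generating spectrum (cosine >= 0.999 at 1e5 draws)."""
        big = simulate_reference(_small_cfg(contig_length_bp=2_000_000, seed=6))
        sig = default_exposure_sbs96()
        rng = np.random.Generator(np.random.PCG64(8))
        _, truth = simulate_clone(big, [_proc(sig, 100_000)], rng, "c")
        freqs = np.zeros(96)
        for ch, n in truth.channel.value_counts().items():
            freqs[SBS96.index[ch]] = n
        assert len(truth) >= 99_000
        assert cosine_similarity(freqs, sig) >= 0.999


class TestStudy:
    def test_clone_counts_and_groups(self, small_study):
        assert len(small_study.control_samples) == 3
        assert len(small_study.exposed_samples) == 4

    def test_written_tree_is_byte_identical_across_runs(self, tmp_path):
        cfg = dict(seed=9, n_contigs=1, contig_length_bp=50_000,
                   background_burden=100, exposure_burden=150, n_genes=4,
                   gene_length_bp=2_000)
        simulate_study(SimulationConfig(**cfg), tmp_path / "a")
        simulate_study(SimulationConfig(**cfg), tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_truth_classification_consistency(self, small_study):
        """Re-classifying every emitted record reproduces the truth
        channel for 100% of records."""
        truth = small_study.truth
        lookup = {}
        for scheme_id, kinds in (
            ("SBS96", ("SNV",)),
            ("DBS78", ("DBS",)),
            ("ID", ("INS", "DEL")),
        ):
            cls, skipped = classify_records(
                small_study.all_records(), small_study.genome, scheme_id
            )
            assert skipped == {}
            for c in cls:
                lookup[(c.record.sample_id, c.record.contig, c.record.pos)] = (
                    c.channel_label
                )
        hits = sum(
            lookup.get((t.sample, t.contig, t.pos)) == t.channel
            for t in truth.itertuples()
        )
        assert hits == len(truth)

    def test_every_vcf_record_has_one_truth_row(self, small_study):
        n_records = sum(len(v) for v in small_study.records.values())
        assert n_records == len(small_study.truth)
        keys = list(zip(small_study.truth["sample"], small_study.truth.contig, small_study.truth.pos))
        assert len(set(keys)) == len(keys)

    def test_zero_exposure_makes_groups_indistinguishable(self):
        """With exposure burden 0, exposed and control clone totals come
        from the same distribution (rank test non-significant in >=19/20
        replicates)."""
        fails = 0
        for rep in range(20):
            cfg = _small_cfg(seed=1000 + rep, exposure_burden=0.0,
                             background_burden=250)
            study = simulate_study(cfg)
            totals = study.truth.groupby("sample").size()
            ctrl = [totals.get(s, 0) for s in study.control_samples]
            expo = [totals.get(s, 0) for s in study.exposed_samples]
            p = stats.mannwhitneyu(ctrl, expo).pvalue
            fails += p <= 0.01
        assert fails <= 1

    def test_genes_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_study(_small_cfg(n_genes=100, gene_length_bp=10_000))

    def test_gene_placement_non_overlapping(self, small_study):
        ivs = sorted(
            (c, s, e) for g in small_study.genes for c, s, e in g.intervals
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or e1 <= s2

    def test_site_index_matches_string_scan(self):
        g = simulate_reference(_small_cfg(contig_length_bp=5_000, seed=12))
        idx = SiteIndex(g)
        seq = g.contigs["chr1"]
        # trinucleotide centres
        for tri in ("ACA", "TTT", "CGC"):
            want = [i + 1 for i in range(len(seq) - 2) if seq[i : i + 3] == tri]
            got = list(idx.tri["chr1"].get(tri, []))
            assert got == want
        # exact-length homopolymer runs (excluding a run at position 0)
        for base in "ACGT":
            for r in (1, 2, 3):
                want = [
                    i
                    for i in range(1, len(seq))
                    if seq[i] == base
                    and (i == 0 or seq[i - 1] != base)
                    and all(seq[j] == base for j in range(i, min(i + r, len(seq))))
                    and i + r <= len(seq)
                    and seq[i : i + r] == base * r
                    and (i + r == len(seq) or seq[i + r] != base)
                ]
                got = list(idx.runs["chr1"].get(base, {}).get(r, []))
                assert got == want
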