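"""Classification of SNVs, doublets and indels to canonical channels."""

import itertools

import numpy as np
import pytest

from exposig.classify import (
    classify_dbs,
    classify_indel,
    classify_sbs,
    merge_adjacent_snvs,
)
from exposig.io import ReferenceGenome
from exposig.schemes import SBS96, revcomp
from exposig.types import MutationRecord, SkipRecord


def snv(contig, pos, ref, alt, sample="s1"):
    return MutationRecord(sample, contig, pos, ref, alt, "SNV")


class TestSbs:
    @pytest.mark.parametrize(
        "seq,pos,ref,alt,expected",
        [
            ("ACC", 2, "C", "A", "A[C>A]C"),   # pyrimidine centre, identity
            ("AGC", 2, "G", "T", "G[C>A]T"),   # purine centre, rc convention
            ("ATG", 2, "T", "C", "A[T>C]G"),   # pyrimidine centre
        ],
    )
    def test_examples(self, seq, pos, ref, alt, expected):
        genome = ReferenceGenome({"c": seq})
        assert classify_sbs(snv("c", pos, ref, alt), genome).channel_label == expected

    def test_edge_context_with_n_is_skipped(self):
        genome = ReferenceGenome({"c": "CGT"})
        with pytest.raises(SkipRecord):
            classify_sbs(snv("c", 1, "C", "A"), genome)

    def test_reference_mismatch_is_an_error(self):
        genome = ReferenceGenome({"c": "AAA"})
        with pytest.raises(ValueError, match="mismatch"):
            classify_sbs(snv("c", 2, "C", "T"), genome)

    def test_exhaustive_trinucleotides_cover_96_channels_twice(self):
        """All 192 (trinucleotide, alt) single-base substitutions fall on
        exactly 96 channels, each hit once per strand."""
        hits: dict[str, int] = {}
        for tri in map("".join, itertools.product("ACGT", repeat=3)):
            genome = ReferenceGenome({"c": tri})
            for alt in "ACGT":
                if alt == tri[1]:
                    continue
                lab = classify_sbs(snv("c", 2, tri[1], alt), genome).channel_label
                hits[lab] = hits.get(lab, 0) + 1
        assert set(hits) == set(SBS96.labels)
        assert all(v == 2 for v in hits.values())


class TestDbs:
    def test_examples(self):
        rec = MutationRecord("s", "c", 5, "CC", "AA", "DBS")
        assert classify_dbs(rec).channel_label == "CC>AA"
        rec = MutationRecord("s", "c", 5, "GG", "TT", "DBS")
        assert classify_dbs(rec).channel_label == "CC>AA"
        rec = MutationRecord("s", "c", 5, "CA", "TG", "DBS")
        assert classify_dbs(rec).channel_label == "TG>CA"

    def test_half_changed_doublet_is_skipped(self):
        rec = MutationRecord("s", "c", 5, "CC", "CA", "DBS")
        with pytest.raises(SkipRecord):
            classify_dbs(rec)


class TestMergeAdjacent:
    def test_adjacent_pair_becomes_dbs(self):
        recs = [snv("chr1", 5, "C", "A"), snv("chr1", 6, "C", "A")]
        merged, flagged = merge_adjacent_snvs(recs)
        assert flagged == []
        assert len(merged) == 1
        assert (merged[0].kind, merged[0].pos, merged[0].ref, merged[0].alt) == (
            "DBS", 5, "CC", "AA",
        )

    def test_non_adjacent_pass_through(self):
        recs = [snv("chr1", 5, "C", "A"), snv("chr1", 7, "C", "A")]
        merged, flagged = merge_adjacent_snvs(recs)
        assert merged == sorted(recs, key=lambda r: r.pos) and flagged == []

    def test_run_of_three_is_flagged_not_merged(self):
        recs = [snv("chr1", p, "C", "A") for p in (5, 6, 7)]
        merged, flagged = merge_adjacent_snvs(recs)
        assert len(merged) == 3 and all(r.kind == "SNV" for r in merged)
        assert len(flagged) == 1 and len(flagged[0]) == 3

    def test_different_samples_never_merge(self):
        recs = [snv("chr1", 5, "C", "A", "a"), snv("chr1", 6, "C", "A", "b")]
        merged, flagged = merge_adjacent_snvs(recs)
        assert len(merged) == 2


class TestIndel:
    def test_single_c_deletion_in_ccc_run(self):
        #            123456789
        genome = ReferenceGenome({"c": "ATACCCGTA"})
        rec = MutationRecord("s", "c", 3, "AC", "A", "DEL")  # deletes one C of CCC
        assert classify_indel(rec, genome).channel_label == "1:Del:C:2"

    def test_g_run_collapses_to_c(self):
        genome = ReferenceGenome({"c": "ATAGGTTA"})
        rec = MutationRecord("s", "c", 3, "AG", "A", "DEL")
        assert classify_indel(rec, genome).channel_label == "1:Del:C:1"

    def test_insertion_next_to_long_t_run_hits_cap(self):
        genome = ReferenceGenome({"c": "GCATTTTTTGC"})
        rec = MutationRecord("s", "c", 3, "A", "AT", "INS")  # +T before TTTTTT
        assert classify_indel(rec, genome).channel_label == "1:Ins:T:5"

    def test_isolated_insertion(self):
        genome = ReferenceGenome({"c": "GCAGAGC"})
        rec = MutationRecord("s", "c", 3, "A", "AT", "INS")
        assert classify_indel(rec, genome).channel_label == "1:Ins:T:0"

    def test_long_deletion_in_repeat(self):
        genome = ReferenceGenome({"c": "TTACGACGACGTT"})
        # delete the first ACG of the ACGx3 tract (left-aligned)
        rec = MutationRecord("s", "c", 2, "TACG", "T", "DEL")
        assert classify_indel(rec, genome).channel_label == "3:Del:R:2"

    def test_long_deletion_with_microhomology(self):
        # deleted TAGC is followed by TAGT: 3-base prefix overlap
        genome = ReferenceGenome({"c": "GGGTAGCTAGTGGG"})
        rec = MutationRecord("s", "c", 3, "GTAGC", "G", "DEL")
        assert classify_indel(rec, genome).channel_label == "4:Del:M:3"

    def test_long_deletion_no_context(self):
        # deleted ACGT: no flanking repeat copy and no prefix/suffix overlap
        genome = ReferenceGenome({"c": "GGCACGTGGG"})
        rec = MutationRecord("s", "c", 3, "CACGT", "C", "DEL")
        assert classify_indel(rec, genome).channel_label == "4:Del:R:0"

    def test_long_insertion_repeat_count(self):
        genome = ReferenceGenome({"c": "TTACGACGTT"})
        rec = MutationRecord("s", "c", 2, "T", "TACG", "INS")  # ACG before ACGx2
        assert classify_indel(rec, genome).channel_label == "3:Ins:R:2"

    def test_run_length_matches_brute_force_scan(self, random_genome):
        """1-bp indel homopolymer length agrees with a direct scan of the
        reference string on >=1000 random events."""
        seq = random_genome.contigs["chr1"]
        rng = np.random.Generator(np.random.PCG64(7))
        checked = 0
        while checked < 1200:
            p0 = int(rng.integers(5, len(seq) - 5))  # 0-based event base
            base = seq[p0]
            anchor = seq[p0 - 1]
            if rng.random() < 0.5:
                rec = MutationRecord("s", "chr1", p0, anchor + base, anchor, "DEL")
                # brute force: run containing p0
                lo = p0
                while lo > 0 and seq[lo - 1] == base:
                    lo -= 1
                hi = p0
                while hi + 1 < len(seq) and seq[hi + 1] == base:
                    hi += 1
                run = hi - lo + 1
                want = f"1:Del:{base if base in 'CT' else revcomp(base)}:{min(run, 6) - 1}"
            else:
                ins_base = "ACGT"[int(rng.integers(4))]
                rec = MutationRecord("s", "chr1", p0, anchor, anchor + ins_base, "INS")
                lo = p0 - 1
                run = 0
                while lo >= 0 and seq[lo] == ins_base:
                    run += 1
                    lo -= 1
                hi = p0
                while hi < len(seq) and seq[hi] == ins_base:
                    run += 1
                    hi += 1
                b = ins_base if ins_base in "CT" else revcomp(ins_base)
                want = f"1:Ins:{b}:{min(run, 5)}"
            got = classify_indel(rec, random_genome).channel_label
            assert got == want, (rec, got, want)
            checked += 1


class TestStrandSymmetry:
    """Classifying a mutation on the opposite strand (reverse-complemented
    genome and alleles) gives the identical channel for all schemes."""

    @staticmethod
    def _rc_genome(genome):
        return ReferenceGenome({c: revcomp(s) for c, s in genome.contigs.items()})

    def test_snv_and_dbs_symmetry(self, random_genome):
        seq = random_genome.contigs["chr1"]
        L = len(seq)
        rc = self._rc_genome(random_genome)
        rng = np.random.Generator(np.random.PCG64(13))
        for _ in range(800):
            p0 = int(rng.integers(1, L - 2))
            ref = seq[p0]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            fwd = classify_sbs(snv("chr1", p0 + 1, ref, alt), random_genome)
            rev = classify_sbs(
                snv("chr1", L - p0, revcomp(ref), revcomp(alt)), rc
            )
            assert fwd.channel_label == rev.channel_label
            # doublet starting at p0
            dref = seq[p0 : p0 + 2]
            dalt = "".join(
                "ACGT"[(("ACGT".index(b)) + 1 + int(rng.integers(3))) % 4] for b in dref
            )
            if dref[0] == dalt[0] or dref[1] == dalt[1]:
                continue
            f = classify_dbs(MutationRecord("s", "chr1", p0 + 1, dref, dalt, "DBS"))
            r = classify_dbs(
                MutationRecord("s", "chr1", L - p0 - 1, revcomp(dref), revcomp(dalt), "DBS")
            )
            assert f.channel_label == r.channel_label

    def test_indel_symmetry(self, random_genome):
        seq = random_genome.contigs["chr1"]
        L = len(seq)
        rc = self._rc_genome(random_genome)
        rng = np.random.Generator(np.random.PCG64(17))
        for _ in range(600):
            ln = int(rng.integers(1, 5))
            p0 = int(rng.integers(2, L - ln - 2))  # 0-based first deleted base
            if rng.random() < 0.5:
                rec = MutationRecord(
                    "s", "chr1", p0, seq[p0 - 1] + seq[p0 : p0 + ln], seq[p0 - 1], "DEL"
                )
                # on the rc strand the deleted segment ends at mirror of p0
                q0 = L - (p0 + ln)  # 0-based start of rc'd deleted segment
                rrec = MutationRecord(
                    "s",
                    "chr1",
                    q0,
                    rc.contigs["chr1"][q0 - 1] + revcomp(seq[p0 : p0 + ln]),
                    rc.contigs["chr1"][q0 - 1],
                    "DEL",
                )
            else:
                ins = "".join("ACGT"[int(rng.integers(4))] for _ in range(ln))
                rec = MutationRecord(
                    "s", "chr1", p0, seq[p0 - 1], seq[p0 - 1] + ins, "INS"
                )
                # fwd insertion between p0-1 and p0 maps to rc insertion
                # between L-p0-1 and L-p0 (0-based), anchor at L-p0-1
                q0 = L - p0
                rrec = MutationRecord(
                    "s",
                    "chr1",
                    q0,
                    rc.contigs["chr1"][q0 - 1],
                    rc.contigs["chr1"][q0 - 1] + revcomp(ins),
                    "INS",
                )
            assert (
                classify_indel(rec, random_genome).channel_label
                == classify_indel(rrec, rc).channel_label
            )
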