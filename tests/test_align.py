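"""Mapping contract: exhaustive oracle, multiplicity filter, seed-index
mapper equivalence, SAM ingestion and the primer screen."""

import numpy as np
import pandas as pd
import pytest

import dissectmap as dm
from dissectmap.align import AlignmentHit, ReadFormatError, SAMFormatError


@pytest.fixture(scope="module")
def tiny_genome():
    rng = np.random.default_rng(42)
    bases = "ACGT"
    seq = "".join(rng.choice(list(bases), 3000))
    unit = "".join(rng.choice(list(bases), 80))
    # plant the same 80-mer at three sites across two scaffolds
    s1 = seq[:1000] + unit + seq[1000:1500] + unit + seq[1500:2000]
    s2 = seq[2000:2500] + unit + seq[2500:]
    return {"tig_a": s1, "tig_b": s2}


class TestEnumerate:
    def test_unique_exact_hit(self, tiny_genome):
        read = tiny_genome["tig_a"][100:120]
        hits = dm.enumerate_alignments(read, tiny_genome, v=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.scaffold, h.pos0, h.mismatches) == ("tig_a", 100, 0)

    def test_repeat_has_three_sites(self, tiny_genome):
        read = tiny_genome["tig_a"][1000:1080]  # the planted 80-mer
        hits = dm.enumerate_alignments(read, tiny_genome, v=2)
        assert len(hits) >= 3

    def test_three_substitutions_exceed_budget(self, tiny_genome):
        read = list(tiny_genome["tig_a"][200:280])
        for i in (5, 40, 70):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        hits = dm.enumerate_alignments("".join(read), tiny_genome, v=2)
        assert hits == []

    def test_rejects_bad_alphabet(self, tiny_genome):
        with pytest.raises(ReadFormatError):
            dm.enumerate_alignments("ACGTX" * 4, tiny_genome, v=0)

    def test_n_counts_as_mismatch_both_ways(self, tiny_genome):
        read = list(tiny_genome["tig_b"][50:70])
        read[7] = "N"
        read = "".join(read)
        # a read N mismatches everything, including a genomic N
        assert dm.enumerate_alignments(read, tiny_genome, v=0) == []
        hits = dm.enumerate_alignments(read, tiny_genome, v=1)
        assert [(h.scaffold, h.pos0, h.mismatches) for h in hits] \
            == [("tig_b", 50, 1)]
        # genomic N also costs a mismatch against an ordinary base
        g = dict(tiny_genome)
        s = list(g["tig_b"])
        s[55] = "N"
        g["tig_b"] = "".join(s)
        clean = tiny_genome["tig_b"][50:70]
        at_site = [h for h in dm.enumerate_alignments(clean, g, v=1)
                   if h.scaffold == "tig_b" and h.pos0 == 50]
        assert [h.mismatches for h in at_site] == [1]


class TestUniqueFilter:
    def test_single_hit_with_two_mismatches_kept(self):
        h = AlignmentHit("r", "s", 0, "+", 2)
        assert dm.unique_filter([h]) == h

    def test_two_hits_suppressed_regardless_of_quality(self):
        hits = [AlignmentHit("r", "s", 0, "+", 0),
                AlignmentHit("r", "s", 500, "+", 2)]
        assert dm.unique_filter(hits, m=1) is None

    def test_no_hits_is_unmapped(self):
        assert dm.unique_filter([]) is None


class TestMapReads:
    def test_oracle_equivalence(self, toy_model, toy_reads):
        """Seed-index mapper == exhaustive scan + multiplicity filter,
        read by read, on a ~100 kb genome."""
        model, _cfg = toy_model
        reads, _truth = toy_reads
        genome = dict(model.scaffold_sequences())
        table = dm.map_reads(reads, genome, v=2, m=1)
        kept = {r.read_id: r for r in table.hits.itertuples(index=False)}
        for rid, seq in reads:
            expected = dm.unique_filter(
                dm.enumerate_alignments(seq, genome, v=2, read_id=rid))
            got = kept.get(rid)
            if expected is None:
                assert got is None, rid
            else:
                assert got is not None, rid
                assert (got.scaffold, got.pos0, got.strand, got.mismatches) \
                    == (expected.scaffold, expected.pos0, expected.strand,
                        expected.mismatches), rid

    def test_counter_conservation(self, toy_model, toy_reads):
        model, _ = toy_model
        table = dm.map_reads(toy_reads[0], dict(model.scaffold_sequences()))
        c = table.counters
        assert c["mapped_unique"] + c["suppressed_multi"] == c["mapped_any"]
        assert c["mapped_any"] + c["unmapped"] == c["total_reads"]

    def test_identity_bound(self, toy_model, toy_reads):
        """Kept 80 bp hits have identity >= (80-2)/80 = 97.5%."""
        model, cfg = toy_model
        table = dm.map_reads(toy_reads[0], dict(model.scaffold_sequences()),
                             v=2)
        L = cfg.read_length
        identity = (L - table.hits["mismatches"]) / L
        assert (identity >= 0.975).all()

    def test_v0_unique_equals_any_without_duplicates(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 5000))
        genome = {"s": seq}
        reads = [(f"r{i}", seq[i * 40:i * 40 + 30]) for i in range(50)]
        table = dm.map_reads(reads, genome, v=0)
        assert table.mapped_unique == table.mapped_any

    def test_strand_symmetry(self, toy_model, toy_reads):
        model, _ = toy_model
        genome = dict(model.scaffold_sequences())
        rc_genome = {k: dm.revcomp(v) for k, v in genome.items()}
        reads = toy_reads[0][:300]
        t1 = dm.map_reads(reads, genome)
        t2 = dm.map_reads(reads, rc_genome)
        assert t1.mapped_unique == t2.mapped_unique
        assert t1.mapped_any == t2.mapped_any

    def test_monotonic_in_v(self, toy_model, toy_reads):
        model, _ = toy_model
        genome = dict(model.scaffold_sequences())
        reads = toy_reads[0][:300]
        any_counts = [dm.map_reads(reads, genome, v=v).mapped_any
                      for v in (0, 1, 2)]
        assert any_counts == sorted(any_counts)

    def test_fixed_length_required(self, tiny_genome):
        with pytest.raises(ReadFormatError, match="fixed-length"):
            dm.map_reads([("a", "ACGTACGTAC"), ("b", "ACGTACG")], tiny_genome)


class TestIngestSam:
    def _write_sam(self, path, records, lengths):
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\n")
            for name, ln in lengths.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
            for rec in records:
                fh.write("\t".join(str(x) for x in rec) + "\n")

    def test_multi_and_unmapped_counting(self, tmp_path):
        sam = tmp_path / "t.sam"
        self._write_sam(sam, [
            ("r1", 0, "s", 1, 255, "10M", "*", 0, 0, "ACGTACGTAC", "*", "NM:i:0"),
            ("r2", 0, "s", 5, 255, "10M", "*", 0, 0, "ACGTACGTAC", "*", "NM:i:1"),
            ("r2", 0, "s", 50, 255, "10M", "*", 0, 0, "ACGTACGTAC", "*", "NM:i:1"),
            ("r3", 4, "*", 0, 0, "*", "*", 0, 0, "ACGTACGTAC", "*"),
        ], {"s": 100})
        table = dm.ingest_sam(sam)
        assert table.counters == {"total_reads": 3, "mapped_any": 2,
                                  "mapped_unique": 1, "suppressed_multi": 1,
                                  "unmapped": 1}
        assert list(table.hits["read_id"]) == ["r1"]

    def test_secondary_records_do_not_multiply(self, tmp_path):
        sam = tmp_path / "t.sam"
        self._write_sam(sam, [
            ("r1", 0, "s", 1, 255, "10M", "*", 0, 0, "ACGTACGTAC", "*"),
            ("r1", 256, "s", 40, 255, "10M", "*", 0, 0, "*", "*"),
        ], {"s": 100})
        table = dm.ingest_sam(sam)
        assert table.mapped_unique == 1

    def test_nh_tag_policy(self, tmp_path):
        sam = tmp_path / "t.sam"
        self._write_sam(sam, [
            ("r1", 0, "s", 1, 255, "10M", "*", 0, 0, "ACGTACGTAC", "*",
             "NM:i:0", "NH:i:2"),
            ("r2", 0, "s", 9, 255, "10M", "*", 0, 0, "ACGTACGTAC", "*",
             "NM:i:0", "NH:i:1"),
        ], {"s": 100})
        table = dm.ingest_sam(sam, policy="tag")
        assert list(table.hits["read_id"]) == ["r2"]

    def test_round_trip_equals_mapper_output(self, toy_model, toy_reads,
                                             tmp_path):
        model, _ = toy_model
        table = dm.map_reads(toy_reads[0], dict(model.scaffold_sequences()))
        sam = tmp_path / "hits.sam"
        table.to_sam(sam, model.lengths(), read_seqs=dict(toy_reads[0]))
        back = dm.ingest_sam(sam)
        assert back.mapped_unique == table.mapped_unique
        a = table.hits.sort_values("read_id").reset_index(drop=True)
        b = back.hits.sort_values("read_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns], check_dtype=False)

    def test_malformed_sam_raises(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:s\tLN:100\n"
                       "r1\tnotaflag\ts\t1\t255\t10M\n")
        with pytest.raises((SAMFormatError, OSError, ValueError)):
            dm.ingest_sam(sam)


class TestPrimerScreen:
    PRIMER = [("p1", "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC")]

    def test_eleven_base_prefix_positive(self):
        read = self.PRIMER[0][1][:11] + "G" * 40
        res = dm.screen_primers([("r", read)], self.PRIMER, min_match_len=11)
        assert res.n_primer_positive == 1

    def test_ten_base_overlap_negative(self):
        read = self.PRIMER[0][1][:10] + "G" * 41
        res = dm.screen_primers([("r", read)], self.PRIMER, min_match_len=11)
        assert res.n_primer_positive == 0

    def test_reverse_complement_detected(self):
        read = "G" * 30 + dm.revcomp(self.PRIMER[0][1][:15])
        res = dm.screen_primers([("r", read)], self.PRIMER, min_match_len=11)
        assert res.n_primer_positive == 1

    def test_chimera_fraction_recovered(self):
        """Unmappable random reads with 30% primer chimeras: positive
        fraction within 3 binomial SD of 0.30."""
        rng = np.random.default_rng(12)
        n = 4000
        reads = []
        primer = self.PRIMER[0][1]
        is_chim = rng.random(n) < 0.30
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), 80))
            if is_chim[i]:
                ins = int(rng.integers(11, len(primer) + 1))
                seq = primer[:ins] + seq[ins:]
            reads.append((f"r{i}", seq))
        res = dm.screen_primers(reads, self.PRIMER, min_match_len=11)
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(res.positive_fraction - 0.30) <= 3 * sd

    def test_empty_primer_file_errors(self):
        with pytest.raises(ValueError):
            dm.screen_primers([("r", "ACGT" * 20)], [], min_match_len=11)

    def test_min_match_len_floor(self):
        with pytest.raises(ValueError):
            dm.screen_primers([], self.PRIMER, min_match_len=5)
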