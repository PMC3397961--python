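"""Tag extraction, mismatch collapse, mapping and TPM normalization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from valvetag import simulate, tagseq
from valvetag.tagseq import (TagCountTable, build_matrix, build_virtual_tag_index,
                             collapse_mismatch, expressed_filter, extract_tags,
                             filter_reads, map_and_aggregate, tpm_normalize)

A17 = "A" * 17


def fastq_record(seq, name="r", flag="N", qual=None):
    qual = qual or "I" * len(seq)
    return f"@{name} 1:{flag}:0:0\n{seq}\n+\n{qual}\n"


class TestFilterReads:
    def test_unflagged_reads_all_pass(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("".join(fastq_record("CATG" + A17, f"r{i}") for i in range(10)))
        reads, rep = filter_reads(p)
        assert len(reads) == 10 and rep["hq_reads"] == 10

    def test_flagged_failures_removed(self, tmp_path):
        p = tmp_path / "r.fastq"
        recs = [fastq_record("CATG" + A17, f"r{i}", flag="Y" if i < 2 else "N")
                for i in range(10)]
        p.write_text("".join(recs))
        reads, rep = filter_reads(p)
        assert rep == {"total_reads": 10, "hq_reads": 8, "failed_reads": 2,
                       "chastity_threshold": 0.6}

    def test_mean_quality_proxy_without_flag(self, tmp_path):
        p = tmp_path / "r.fastq"
        good = f"@r1\n{'CATG' + A17}\n+\n{'I' * 21}\n"
        bad = f"@r2\n{'CATG' + A17}\n+\n{'#' * 21}\n"
        p.write_text(good + bad)
        reads, rep = filter_reads(p)
        assert len(reads) == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("")
        reads, rep = filter_reads(p)
        assert reads == [] and rep["total_reads"] == 0

    def test_malformed_record_reports_index(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nCATGAA\n+\nIII\n")  # quality length mismatch
        with pytest.raises(ValueError, match="record"):
            filter_reads(p)


class TestExtractTags:
    def test_tag_is_first_21_bases(self):
        t = extract_tags(["CATG" + A17 + "GGGGGGG"])
        assert t.counts == {"CATG" + A17: 1}

    def test_unanchored_read_discarded(self):
        rep = {}
        t = extract_tags(["GATC" + A17 + "CCC"], report=rep)
        assert t.counts == {} and rep["unanchored"] == 1

    def test_identical_reads_accumulate(self):
        t = extract_tags(["CATG" + A17] * 3)
        assert t.counts["CATG" + A17] == 3

    def test_short_and_n_reads_discarded(self):
        rep = {}
        t = extract_tags(["CATGAA", "CATG" + "N" * 17], report=rep)
        assert t.counts == {} and rep["short"] == 1 and rep["with_n"] == 1

    def test_case_insensitive(self):
        t = extract_tags(["catg" + A17.lower()])
        assert t.counts == {"CATG" + A17: 1}


def table(counts, lib="lib"):
    return TagCountTable(lib, dict(counts), sum(counts.values()), sum(counts.values()))


class TestCollapseMismatch:
    def test_satellite_of_highly_expressed_parent_removed(self):
        parent = "CATG" + A17
        sat = "CATG" + "C" + A17[1:]
        out, rep = collapse_mismatch(table({parent: 100_000, sat: 8}))
        assert sat not in out.counts and parent in out.counts
        assert rep["removed_tag_count"] == 8

    def test_moderate_neighbours_both_kept(self):
        a = "CATG" + A17
        b = "CATG" + "C" + A17[1:]
        out, _ = collapse_mismatch(table({a: 600, b: 550}))
        assert set(out.counts) == {a, b}

    def test_ratio_unmet_keeps_satellite(self):
        a = "CATG" + A17
        b = "CATG" + "C" + A17[1:]
        out, _ = collapse_mismatch(table({a: 2000, b: 50}))  # 2000 < 100 x 50
        assert set(out.counts) == {a, b}

    def test_isolated_tag_retained(self):
        a = "CATG" + A17
        out, _ = collapse_mismatch(table({a: 1}))
        assert a in out.counts

    def test_no_chaining(self):
        """A satellite of a satellite is judged against original counts only."""
        a = "CATG" + A17                      # 100,000
        b = "CATG" + "C" + A17[1:]            # 900: removed (vs a)
        c = "CATG" + "CC" + A17[2:]           # 5: distance 2 from a, 1 from b
        out, _ = collapse_mismatch(table({a: 100_000, b: 900, c: 5}))
        assert b not in out.counts
        # b (count 900 < parent_min) cannot remove c even though 900 >= 100x5
        assert c in out.counts

    def test_order_independence(self):
        tags = {"CATG" + A17: 100_000,
                "CATG" + "C" + A17[1:]: 8,
                "CATG" + A17[:-1] + "G": 3,
                "CATG" + "GG" + A17[2:]: 50}
        results = []
        for perm in itertools.permutations(tags.items()):
            out, _ = collapse_mismatch(table(dict(perm)))
            results.append(dict(sorted(out.counts.items())))
        assert all(r == results[0] for r in results)


class TestVirtualTagIndex:
    def test_three_prime_most_tag_is_rank_one(self):
        seq = "CATG" + "A" * 17 + "TTTT" + "CATG" + "C" * 17 + "GGGGG"
        idx = build_virtual_tag_index({"g1": seq})
        assert ("g1", "sense", 1) in idx.hits["CATG" + "C" * 17]
        assert ("g1", "sense", 2) in idx.hits["CATG" + "A" * 17]

    def test_shared_tag_flagged_ambiguous(self):
        seq = "CATG" + "A" * 17 + "GGGGG"
        idx = build_virtual_tag_index({"g1": seq, "g2": "TT" + seq})
        assert idx.is_ambiguous("CATG" + "A" * 17)

    def test_reverse_complement_is_antisense(self):
        from valvetag.tagseq import _revcomp
        tag = "CATG" + "A" * 10 + "CCCCCCC"
        seq = "GGG" + _revcomp(tag) + "GGG"
        idx = build_virtual_tag_index({"g1": seq})
        hits = idx.hits.get(tag, [])
        assert hits and all(ori == "antisense" for _, ori, _ in hits)
        assert idx.sense_genes(tag) == []

    def test_untaggable_gene_reported(self):
        idx = build_virtual_tag_index({"g1": "A" * 50})
        assert idx.untaggable_genes == ["g1"]


class TestMapAndAggregate:
    def test_variant_tags_summed_per_gene(self):
        seq = "CATG" + "A" * 17 + "TT" + "CATG" + "C" * 17 + "GGGGG"
        idx = build_virtual_tag_index({"g1": seq})
        counts, rep = map_and_aggregate(
            table({"CATG" + "C" * 17: 30, "CATG" + "A" * 17: 12}), idx)
        assert counts["g1"] == 42

    def test_ambiguous_tag_excluded_and_reported(self):
        seq = "CATG" + "A" * 17 + "GGGGG"
        idx = build_virtual_tag_index({"g1": seq, "g2": "TT" + seq})
        counts, rep = map_and_aggregate(table({"CATG" + "A" * 17: 500}), idx)
        assert len(counts) == 0
        assert rep["ambiguous_count"] == 500

    def test_unmapped_tag_excluded_and_reported(self):
        idx = build_virtual_tag_index({"g1": "CATG" + "G" * 17 + "AAAAA"})
        counts, rep = map_and_aggregate(table({"CATG" + "T" * 17: 7}), idx)
        assert len(counts) == 0 and rep["unmapped_count"] == 7


class TestTpm:
    def test_printed_library_worked_example(self):
        """A raw count of 5,577 over 6,075,421 HQ tags is 918.0 TPM (1 d.p.)."""
        m = build_matrix({"avc": pd.Series({"Twist1": 5577})}, {"avc": 6_075_421})
        m = tpm_normalize(m)
        assert round(float(m.tpm.loc["Twist1", "avc"]), 1) == 918.0

    def test_zero_raw_zero_tpm_and_unit_denominator(self):
        m = tpm_normalize(build_matrix(
            {"l": pd.Series({"a": 0, "b": 7})}, {"l": 1_000_000}))
        assert float(m.tpm.loc["a", "l"]) == 0.0
        assert float(m.tpm.loc["b", "l"]) == 7.0

    def test_zero_denominator_is_hard_error(self):
        with pytest.raises(ValueError, match="denominator"):
            tpm_normalize(build_matrix({"l": pd.Series({"a": 1})}, {"l": 0}))

    def test_tag_level_tpm_conserved(self):
        rng = np.random.default_rng(0)
        counts = pd.Series(rng.integers(1, 1000, 500),
                           index=[f"t{i}" for i in range(500)])
        m = tpm_normalize(build_matrix({"l": counts}, {"l": int(counts.sum())}))
        assert float(m.tpm["l"].sum()) == pytest.approx(1e6, rel=1e-6)


class TestExpressedFilter:
    @pytest.mark.parametrize("count,expressed", [(0, False), (5, False), (6, True)])
    def test_threshold(self, count, expressed):
        assert bool(expressed_filter(pd.Series([count]))[0]) is expressed


class TestMatrixIO:
    def test_roundtrip(self, tmp_path):
        m = tpm_normalize(build_matrix(
            {"a": pd.Series({"g1": 5, "g2": 10}), "b": pd.Series({"g1": 3})},
            {"a": 100, "b": 200}))
        tagseq.write_matrix(m, tmp_path / "m.tsv")
        back = tagseq.read_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.raw, m.raw)
        pd.testing.assert_series_equal(back.denominators.astype(float),
                                       m.denominators.astype(float))
        pd.testing.assert_frame_equal(back.tpm, m.tpm)


class TestPipelineRoundTrip:
    def test_zero_error_recovery_is_exact(self, small_cfg, small_tx, small_counts, tmp_path):
        """FASTQ -> filter -> extract recovers the truth tag counts exactly."""
        lib = "avc"
        fq = tmp_path / f"{lib}.fastq"
        simulate.simulate_reads(small_counts[lib], small_tx, small_cfg, lib, fq)
        t, _ = tagseq.count_library(fq, lib)
        tag_of = dict(zip(small_tx.tags["gene_id"], small_tx.tags["tag"]))
        expected = {tag_of[g]: int(c) for g, c in small_counts[lib].items() if c > 0}
        assert t.counts == expected

    def test_gene_level_tpm_sum_bounded(self, small_cfg, small_tx, small_counts, tmp_path):
        lib = "oft"
        fq = tmp_path / f"{lib}.fastq"
        simulate.simulate_reads(small_counts[lib], small_tx, small_cfg, lib, fq)
        t, _ = tagseq.count_library(fq, lib)
        idx = build_virtual_tag_index(small_tx.sequences)
        gc, _ = map_and_aggregate(t, idx)
        m = tpm_normalize(build_matrix({lib: gc}, {lib: t.total_tags()}))
        assert float(m.tpm[lib].sum()) <= 1e6 * (1 + 1e-9)
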