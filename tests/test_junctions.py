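"""Reference junction construction, chain correction and exon couplings."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from isocouple.errors import ParseError, UsageError
from isocouple.junctions import (
    JunctionDB,
    JunctionRecord,
    annotation_junctions,
    calculate_exon_couplings,
    correct_junctions,
    create_reference_junctions,
    parse_star_sj,
    read_to_junctions,
    residual_frame,
)
from isocouple.simulate import SimConfig, generate_annotation, simulate_reads, write_star_sj

from conftest import build_bundle
from test_annotation import make_exon


def write_sj(path: Path, rows) -> Path:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")
    return path


class TestParseStarSj:
    def test_min_jcounts_filter(self, tmp_path):
        sj = write_sj(
            tmp_path / "sj.tab",
            [("chr2L", 100, 200, 1, 0, 1, 1, 0, 30),
             ("chr2L", 300, 400, 1, 0, 1, 5, 0, 30)],
        )
        recs = parse_star_sj(sj, min_jcounts=2)
        assert len(recs) == 1
        assert recs[0].short_read_count == 5

    def test_coordinate_and_strand_conversion(self, tmp_path):
        sj = write_sj(tmp_path / "sj.tab", [("chr2L", 100, 200, 1, 0, 1, 5, 0, 30)])
        (rec,) = parse_star_sj(sj)
        assert (rec.start, rec.end, rec.strand) == (99, 200, "+")

    def test_undefined_strand_dropped(self, tmp_path):
        sj = write_sj(
            tmp_path / "sj.tab",
            [("chr2L", 100, 200, 0, 0, 1, 9, 0, 30),
             ("chr2L", 300, 400, 2, 0, 1, 9, 0, 30)],
        )
        recs = parse_star_sj(sj)
        assert len(recs) == 1
        assert recs[0].strand == "-"

    def test_column_mismatch_rejected(self, tmp_path):
        bad = tmp_path / "bad.tab"
        bad.write_text("chr1\t100\t200\t1\n")
        with pytest.raises(ParseError, match="9 columns"):
            parse_star_sj(bad)


class TestCreateReferenceJunctions:
    def exons(self):
        # transcript with two introns: [200,500) and [700,900)
        return [
            make_exon(100, 200, tx="t1"),
            make_exon(500, 700, tx="t1"),
            make_exon(900, 1100, tx="t1"),
        ]

    def test_annotation_junctions_from_consecutive_exons(self):
        recs = annotation_junctions(self.exons())
        assert {(r.start, r.end) for r in recs} == {(200, 500), (700, 900)}
        assert all(r.support == "annotation" for r in recs)

    def test_union_marks_shared_junctions_both(self, tmp_path):
        sj = write_sj(
            tmp_path / "sj.tab",
            [("chr1", 201, 500, 1, 0, 1, 7, 0, 30),      # duplicates annotation
             ("chr1", 1201, 1400, 1, 0, 0, 4, 0, 30)],   # novel
        )
        db = create_reference_junctions(sj, self.exons(), type="short")
        by_key = {(r.start, r.end): r for r in db.records}
        assert by_key[(200, 500)].support == "both"
        assert by_key[(200, 500)].short_read_count == 7
        assert by_key[(1200, 1400)].support == "short_read"
        assert by_key[(700, 900)].support == "annotation"

    def test_annotation_type_ignores_sj_file(self, tmp_path):
        sj = write_sj(tmp_path / "sj.tab", [("chr1", 1201, 1400, 1, 0, 0, 9, 0, 30)])
        db = create_reference_junctions(sj, self.exons(), type="annotation")
        assert {(r.start, r.end) for r in db.records} == {(200, 500), (700, 900)}

    def test_save_load_roundtrip(self, tmp_path):
        db = create_reference_junctions(None, self.exons(), type="annotation")
        db.save(tmp_path / "jdb")
        loaded = JunctionDB.load(tmp_path / "jdb")
        assert [r.key for r in loaded.records] == [r.key for r in db.records]


class TestCorrectJunctions:
    def db(self):
        return JunctionDB(
            [
                JunctionRecord("chr1", 600, 1600, "+", "annotation"),
                JunctionRecord("chr1", 2000, 2600, "+", "annotation"),
                JunctionRecord("chr1", 2012, 2600, "+", "annotation"),
            ]
        )

    def test_snap_within_tolerance(self):
        res = correct_junctions([(603, 1597)], self.db(), "chr1", "+", tol=10)
        assert res.status == "snapped"
        assert res.chain == [(600, 1600)]

    def test_exact_chain_unchanged(self):
        res = correct_junctions([(600, 1600), (2000, 2600)], self.db(), "chr1", "+")
        assert res.status == "exact"
        assert res.chain == [(600, 1600), (2000, 2600)]

    def test_novel_junction_rejected(self):
        res = correct_junctions([(100, 300)], self.db(), "chr1", "+", tol=10)
        assert (res.status, res.reason) == ("rejected", "novel_junction")

    def test_ambiguous_rejected_unless_snap_closest(self):
        res = correct_junctions([(2005, 2600)], self.db(), "chr1", "+", tol=10)
        assert (res.status, res.reason) == ("rejected", "ambiguous_junction")
        res = correct_junctions(
            [(2005, 2600)], self.db(), "chr1", "+", tol=10, snap_closest=True
        )
        assert res.chain == [(2000, 2600)]

    def test_boundary_never_moves_more_than_tol(self):
        rng = np.random.default_rng(4)
        db = self.db()
        for _ in range(200):
            s = 600 + int(rng.integers(-20, 21))
            e = 1600 + int(rng.integers(-20, 21))
            res = correct_junctions([(s, e)], db, "chr1", "+", tol=8)
            if res.status != "rejected":
                (cs, ce) = res.chain[0]
                assert abs(cs - s) <= 8 and abs(ce - e) <= 8

    def test_shrinking_tol_monotone(self):
        rng = np.random.default_rng(14)
        db = self.db()
        introns = [
            (600 + int(rng.integers(-15, 16)), 1600 + int(rng.integers(-15, 16)))
            for _ in range(300)
        ]
        accepted = []
        for tol in (15, 10, 5, 2, 0):
            n = sum(
                correct_junctions([iv], db, "chr1", "+", tol=tol).status != "rejected"
                for iv in introns
            )
            accepted.append(n)
        assert accepted == sorted(accepted, reverse=True)


class TestReadToJunctions:
    def test_inclusion_tables_match_truth_at_zero_noise(self, tmp_path):
        cfg = SimConfig(
            n_genes=2, n_reads=150, seed=33,
            end_jitter_sd=0.0, truncation_fraction=0.0, junction_noise=0,
            inclusion_probs=[np.array([[0.8, 1.0], [0.2, 1.0]])] * 2,
        )
        b = build_bundle(tmp_path / "zn", cfg)
        jdb = create_reference_junctions(b.sj, b.exons, type="short")
        counts = read_to_junctions(b.bam, jdb, b.db, tol=5)
        assert counts.correction_stats["rejected"] == 0
        assert counts.correction_stats["snapped"] == 0
        # truth: inclusion of the exon1 entry junction per TSS
        truth = b.truth
        for lay in b.layouts:
            jkey = (lay.contig, *lay.junction_genomic(0, 1), lay.strand)
            inc, exc = counts.tables[lay.gene_id][jkey]["TSS"]
            sub = truth[truth.gene_id == lay.gene_id]
            for i in range(cfg.n_tss):
                tssid = lay.tss_id(i)
                expected = sum(
                    1
                    for chain in sub[sub.tss_id == tssid].chain
                    if f"{lay.junction_genomic(0, 1)[0]}-{lay.junction_genomic(0, 1)[1]}"
                    in chain.split(";")
                )
                assert inc.get(tssid, 0) == expected

    def test_corrected_chains_equal_truth_when_tol_covers_noise(self, tmp_path):
        cfg = SimConfig(
            n_genes=2, n_reads=100, seed=34,
            end_jitter_sd=0.0, truncation_fraction=0.0, junction_noise=4,
        )
        b = build_bundle(tmp_path / "nz", cfg)
        jdb = create_reference_junctions(b.sj, b.exons, type="short")
        counts = read_to_junctions(b.bam, jdb, b.db, tol=10)
        assert counts.correction_stats["rejected"] == 0
        reads = pd.DataFrame(counts.reads).set_index("read_id")
        truth = b.truth.set_index("read_id")
        joined = truth.join(reads, rsuffix="_called")
        assert (joined.chain == joined.chain_called).all()

    def test_accounting_partition(self, noisy_bundle):
        b = noisy_bundle
        jdb = create_reference_junctions(b.sj, b.exons, type="short")
        counts = read_to_junctions(b.bam, jdb, b.db, tol=10)
        s = counts.correction_stats
        assert s["exact"] + s["snapped"] + s["rejected"] == len(counts.reads)


class TestCalculateExonCouplings:
    def coupled_bundle(self, tmp_path):
        # exon 1 included 90% under TSS1 vs 10% under TSS2; exon 2 constitutive
        cfg = SimConfig(
            n_genes=2, n_reads=200, seed=55,
            inclusion_probs=[np.array([[0.9, 1.0], [0.1, 1.0]])] * 2,
        )
        return build_bundle(tmp_path / "cj", cfg)

    def test_junction_tss_coupling_detected_with_correct_signs(self, tmp_path):
        b = self.coupled_bundle(tmp_path)
        jdb = create_reference_junctions(b.sj, b.exons, type="short")
        counts = read_to_junctions(b.bam, jdb, b.db, tol=10)
        results = calculate_exon_couplings(counts, seed=6)
        res = residual_frame(results)
        for lay in b.layouts:
            js, je = lay.junction_genomic(0, 1)  # exon1 entry junction
            row = results[
                (results.gene_id == lay.gene_id)
                & (results.junction_start == js)
                & (results.junction_end == je)
                & (results.axis == "TSS")
            ].iloc[0]
            assert row.tested and row.coupled and row.q_value <= 0.01
            rsub = res[
                (res.gene_id == lay.gene_id)
                & (res.junction_start == js)
                & (res.junction_end == je)
                & (res.axis == "TSS")
            ].set_index("cluster_id")
            assert rsub.loc[lay.tss_id(0), "residual"] > 0  # enriched under TSS1
            assert rsub.loc[lay.tss_id(1), "residual"] < 0

    def test_constitutive_junction_not_testable(self, tmp_path):
        b = self.coupled_bundle(tmp_path)
        jdb = create_reference_junctions(b.sj, b.exons, type="short")
        counts = read_to_junctions(b.bam, jdb, b.db, tol=10)
        results = calculate_exon_couplings(counts, seed=6)
        for lay in b.layouts:
            js, je = lay.junction_genomic(2, 3)  # exit of constitutive exon 2
            sub = results[
                (results.gene_id == lay.gene_id)
                & (results.junction_start == js)
                & (results.junction_end == je)
            ]
            assert not sub.tested.any()  # exclusion row is (almost) empty

    def test_uniform_inclusion_not_coupled(self, tmp_path):
        cfg = SimConfig(
            n_genes=2, n_reads=300, seed=56,
            inclusion_probs=[np.array([[0.5, 1.0], [0.5, 1.0]])] * 2,
        )
        b = build_bundle(tmp_path / "uj", cfg)
        jdb = create_reference_junctions(b.sj, b.exons, type="short")
        counts = read_to_junctions(b.bam, jdb, b.db, tol=10)
        results = calculate_exon_couplings(counts, seed=7, alpha=0.001)
        assert not results.coupled.any()
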