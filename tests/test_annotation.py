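"""Annotation parsing, end clustering and isoform-database construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isocouple.annotation import (
    ExonRecord,
    ExternalEnd,
    GenomicInterval,
    add_end_database,
    cluster_positions,
    parse_annotation,
    prepare_isoform_database,
    transcript_ends,
)
from isocouple.errors import (
    DataError,
    EmptyDatabaseError,
    ParseError,
    UsageError,
)

from conftest import write_gtf


def make_exon(s, e, strand="+", gene="g", tx="t", contig="chr1"):
    return ExonRecord(GenomicInterval(contig, s, e, strand), gene, tx, "protein_coding")


def brute_force_single_linkage(positions, window):
    """Oracle: transitive closure of |a-b| <= window over all pairs."""
    pos = sorted(positions)
    groups = [[p] for p in pos]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups) - 1):
            if any(
                abs(a - b) <= window for a in groups[i] for b in groups[i + 1]
            ):
                groups[i] += groups.pop(i + 1)
                merged = True
                break
    return [sorted(g) for g in groups]


class TestParseAnnotation:
    def test_biotype_filter_keeps_coding_exons(self, two_gene_gtf):
        recs = parse_annotation(two_gene_gtf, biotype_filter="protein_coding")
        assert len(recs) == 3
        assert {r.gene_id for r in recs} == {"pcg1"}

    def test_no_filter_keeps_all(self, two_gene_gtf):
        recs = parse_annotation(two_gene_gtf, biotype_filter=None)
        assert len(recs) == 5

    def test_coordinates_converted_to_half_open(self, tmp_path):
        gtf = write_gtf(
            tmp_path / "x.gtf",
            [("chr1", 100, 200, "+", "g", "t", "protein_coding")],
        )
        (rec,) = parse_annotation(gtf)
        assert (rec.interval.start, rec.interval.end) == (100, 200)

    def test_minus_strand_passthrough(self, tmp_path):
        gtf = write_gtf(
            tmp_path / "m.gtf",
            [("chr1", 100, 200, "-", "g", "t", "protein_coding")],
        )
        (rec,) = parse_annotation(gtf)
        assert rec.interval.strand == "-"

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            "chr1\tbroken line\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            parse_annotation(path, biotype_filter=None)

    def test_empty_after_filter_raises(self, two_gene_gtf):
        with pytest.raises(EmptyDatabaseError):
            parse_annotation(two_gene_gtf, biotype_filter="rRNA")


class TestTranscriptEnds:
    def test_plus_strand(self):
        ends = transcript_ends([make_exon(100, 200), make_exon(500, 600)])
        assert ends["t"][3:] == (100, 600)

    def test_minus_strand_swaps_roles(self):
        ends = transcript_ends(
            [make_exon(100, 200, "-"), make_exon(500, 600, "-")]
        )
        assert ends["t"][3:] == (600, 100)

    def test_single_exon(self):
        ends = transcript_ends([make_exon(0, 50)])
        assert ends["t"][3:] == (0, 50)

    def test_mixed_strands_rejected(self):
        with pytest.raises(DataError):
            transcript_ends([make_exon(0, 50, "+"), make_exon(100, 150, "-")])


class TestClusterPositions:
    def test_merge_and_split(self):
        clusters = cluster_positions([100, 130, 400], 50)
        assert [c[0] for c in clusters] == [[100, 130], [400]]

    def test_chaining_beyond_window(self):
        clusters = cluster_positions([0, 50, 100], 50)
        assert [c[0] for c in clusters] == [[0, 50, 100]]

    def test_singleton(self):
        assert cluster_positions([7], 1000) == [([7], 7)]

    def test_modal_representative_tie_is_five_prime_most(self):
        members, rep = cluster_positions([10, 10, 20, 20], 50, strand="+")[0]
        assert rep == 10
        members, rep = cluster_positions([10, 10, 20, 20], 50, strand="-")[0]
        assert rep == 20

    def test_negative_window_rejected(self):
        with pytest.raises(UsageError):
            cluster_positions([1, 2], -1)

    @settings(derandomize=True, max_examples=100)
    @given(
        positions=st.lists(st.integers(0, 500), min_size=1, max_size=50),
        window=st.integers(0, 60),
    )
    def test_matches_brute_force_oracle(self, positions, window):
        got = [c[0] for c in cluster_positions(positions, window)]
        assert got == brute_force_single_linkage(positions, window)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pos = list(rng.integers(0, 1000, size=30))
        base = cluster_positions(pos, 40)
        for _ in range(5):
            rng.shuffle(pos)
            assert cluster_positions(pos, 40) == base

    def test_monotone_coarsening(self):
        rng = np.random.default_rng(6)
        pos = list(rng.integers(0, 2000, size=40))
        n_prev = None
        for window in (0, 10, 50, 200, 1000):
            n = len(cluster_positions(pos, window))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


def two_tss_two_tes_exons():
    return [
        make_exon(1000, 2000, tx="t1"),
        make_exon(3000, 5000, tx="t1"),
        make_exon(1020, 2000, tx="t2"),
        make_exon(3000, 5400, tx="t2"),
    ]


class TestPrepareIsoformDatabase:
    def test_windows_merge_and_separate(self):
        # TSS 1000/1020 merge under window 50; TES 5000/5400 split under 150
        db = prepare_isoform_database(two_tss_two_tes_exons())
        g = db.genes["g"]
        assert (len(g.tss), len(g.tes), len(g.pairs)) == (1, 2, 2)

    def test_zero_window_splits_everything(self):
        db = prepare_isoform_database(two_tss_two_tes_exons(), tss_window=0)
        g = db.genes["g"]
        assert (len(g.tss), len(g.pairs)) == (2, 4)

    def test_single_transcript_gene(self):
        db = prepare_isoform_database([make_exon(10, 500)])
        g = db.genes["g"]
        assert (len(g.tss), len(g.tes), len(g.pairs)) == (1, 1, 1)

    def test_pairs_are_cross_product(self, noisy_bundle):
        for g in noisy_bundle.db.genes.values():
            assert len(g.pairs) <= len(g.tss) * len(g.tes)
            assert len(g.pairs) == len(g.tss) * len(g.tes)  # no orientation losses

    def test_cluster_ids_ordered_five_to_three(self, noisy_bundle):
        for g in noisy_bundle.db.genes.values():
            reps = [c.representative for c in g.tss]
            assert reps == sorted(reps, reverse=(g.strand == "-"))
            assert [c.cluster_id for c in g.tss] == [
                f"{g.gene_id}:TSS{i + 1}" for i in range(len(g.tss))
            ]

    def test_save_load_roundtrip(self, noisy_bundle, tmp_path):
        db = noisy_bundle.db
        db.save(tmp_path / "db")
        loaded = type(db).load(tmp_path / "db")
        assert loaded.tss_window == db.tss_window
        for gid, g in db.genes.items():
            lg = loaded.genes[gid]
            assert [c.representative for c in lg.tss] == [
                c.representative for c in g.tss
            ]
            assert lg.pairs == g.pairs

    def test_gtf_export_roundtrip(self, noisy_bundle, tmp_path):
        """Rebuilding from the exported GTF reproduces clusters and pairs."""
        db = noisy_bundle.db
        out = tmp_path / "db.gtf"
        db.to_gtf(out)
        db2 = prepare_isoform_database(
            parse_annotation(out), db.tss_window, db.tes_window
        )
        assert set(db2.genes) == set(db.genes)
        for gid, g in db.genes.items():
            g2 = db2.genes[gid]
            assert [c.representative for c in g2.tss] == [
                c.representative for c in g.tss
            ]
            assert [c.representative for c in g2.tes] == [
                c.representative for c in g.tes
            ]
            assert g2.pairs == g.pairs


class TestAddEndDatabase:
    def db(self):
        return prepare_isoform_database(two_tss_two_tes_exons())

    def test_absorbed_within_window(self):
        db = self.db()
        ext = [ExternalEnd(GenomicInterval("chr1", 1030, 1031, "+"), "TSS")]
        out = add_end_database(db, ext, "TSS", window=50)
        g = out.genes["g"]
        assert len(g.tss) == 1
        assert g.tss[0].representative == db.genes["g"].tss[0].representative
        assert 1030 in g.tss[0].member_positions

    def test_new_cluster_re_enumerates_pairs(self):
        db = self.db()
        ext = [ExternalEnd(GenomicInterval("chr1", 2500, 2501, "+"), "TSS")]
        out = add_end_database(db, ext, "TSS", window=50)
        g = out.genes["g"]
        assert len(g.tss) == 2
        assert len(g.pairs) == len(g.tss) * len(g.tes)

    def test_empty_external_is_identity(self):
        db = self.db()
        out = add_end_database(db, [], "TSS", window=50)
        assert out.genes["g"].pairs == db.genes["g"].pairs
        assert [c.representative for c in out.genes["g"].tss] == [
            c.representative for c in db.genes["g"].tss
        ]

    def test_kind_mismatch_rejected(self):
        db = self.db()
        ext = [ExternalEnd(GenomicInterval("chr1", 1030, 1031, "+"), "TES")]
        with pytest.raises(UsageError):
            add_end_database(db, ext, "TSS", window=50)

    def test_unassignable_records_skipped(self):
        db = self.db()
        ext = [ExternalEnd(GenomicInterval("chr9", 10, 11, "+"), "TSS")]
        out = add_end_database(db, ext, "TSS", window=50)
        assert len(out.genes["g"].tss) == 1
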