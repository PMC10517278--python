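"""Full-length read filtering and 5'-3' link counting.

Aligned long reads are reduced to a strand-aware 5' end, 3' end and intron
chain.  A read is *full length* when both ends fall inside the assignment
window of a TSS and a TES cluster of the same gene; those reads are
tallied into per-gene TSS x TES contingency tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import pysam

from .annotation import Gene, GeneIndex, IsoformDatabase
from .errors import ConsistencyError, MissingIndexError

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 10

# CIGAR operations that consume the reference
_REF_OPS = {0, 2, 3, 7, 8}  # M, D, N, =, X
_INTRON_OP = 3

STATUS_ORDER = (
    "full_length", "no_tss", "no_tes", "ambiguous_gene", "unassigned", "filtered",
)


@dataclass
class ReadFeatures:
    """One primary alignment reduced to ends and intron chain."""

    read_id: str
    contig: str
    aln_strand: str
    start: int
    end: int
    five_prime: int
    three_prime: int
    introns: list[tuple[int, int]]
    mapq: int
    flags: int


@dataclass
class ReadAssignment:
    read_id: str
    gene_id: str = ""
    tss_id: str = ""
    tes_id: str = ""
    status: str = "unassigned"


@dataclass
class LinkCounts:
    """Per-gene TSS x TES count matrices plus per-read assignments."""

    matrices: dict[str, np.ndarray] = field(default_factory=dict)
    tss_ids: dict[str, list[str]] = field(default_factory=dict)
    tes_ids: dict[str, list[str]] = field(default_factory=dict)
    assignments: list[ReadAssignment] = field(default_factory=list)
    totals: dict[str, int] = field(default_factory=dict)

    def gene_table(self, gene_id: str) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrices[gene_id],
            index=self.tss_ids[gene_id],
            columns=self.tes_ids[gene_id],
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.matrices):
            m = self.matrices[gid]
            for i, tss in enumerate(self.tss_ids[gid]):
                for j, tes in enumerate(self.tes_ids[gid]):
                    rows.append((gid, tss, tes, int(m[i, j])))
        return pd.DataFrame(rows, columns=["gene_id", "tss_id", "tes_id", "count"])

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.read_id, a.gene_id, a.tss_id, a.tes_id, a.status) for a in self.assignments],
            columns=["read_id", "gene_id", "tss_id", "tes_id", "status"],
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(directory / "counts.tsv", sep="\t", index=False)
        self.assignment_frame().to_csv(
            directory / "read_assignments.txt", sep="\t", index=False
        )
        (directory / "totals.json").write_text(json.dumps(self.totals, indent=2))

    @classmethod
    def load(cls, directory: str | Path, db: IsoformDatabase) -> "LinkCounts":
        directory = Path(directory)
        counts = pd.read_csv(directory / "counts.tsv", sep="\t")
        obj = cls(totals=json.loads((directory / "totals.json").read_text()))
        _init_matrices(obj, db)
        for r in counts.itertuples(index=False):
            i = obj.tss_ids[r.gene_id].index(r.tss_id)
            j = obj.tes_ids[r.gene_id].index(r.tes_id)
            obj.matrices[r.gene_id][i, j] = r.count
        apath = directory / "read_assignments.txt"
        if apath.exists():
            adf = pd.read_csv(apath, sep="\t", keep_default_na=False)
            obj.assignments = [
                ReadAssignment(r.read_id, r.gene_id, r.tss_id, r.tes_id, r.status)
                for r in adf.itertuples(index=False)
            ]
        return obj


def _init_matrices(counts: LinkCounts, db: IsoformDatabase) -> None:
    for gid, g in db.genes.items():
        counts.tss_ids[gid] = [c.cluster_id for c in g.tss]
        counts.tes_ids[gid] = [c.cluster_id for c in g.tes]
        counts.matrices[gid] = np.zeros((len(g.tss), len(g.tes)), dtype=np.int64)


# ------------------------------------------------------------- BAM parsing


def _features_from_alignment(aln: pysam.AlignedSegment) -> ReadFeatures:
    pos = aln.reference_start
    introns: list[tuple[int, int]] = []
    for op, length in aln.cigartuples:
        if op == _INTRON_OP:
            introns.append((pos, pos + length))
        if op in _REF_OPS:
            pos += length
    strand = "-" if aln.is_reverse else "+"
    start, end = aln.reference_start, pos
    five, three = (start, end) if strand == "+" else (end, start)
    return ReadFeatures(
        read_id=aln.query_name,
        contig=aln.reference_name,
        aln_strand=strand,
        start=start,
        end=end,
        five_prime=five,
        three_prime=three,
        introns=introns,
        mapq=aln.mapping_quality,
        flags=aln.flag,
    )


def extract_read_features(
    bam_path: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    stats: dict[str, int] | None = None,
) -> Iterator[ReadFeatures]:
    """Yield :class:`ReadFeatures` for primary alignments passing MAPQ.

    Secondary, supplementary, unmapped and CIGAR-less records are skipped;
    skip reasons are tallied into ``stats`` when given.
    """
    bam_path = Path(bam_path)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        try:
            bam.check_index()
        except (ValueError, AttributeError) as exc:
            raise MissingIndexError(
                f"{bam_path} has no index; run `samtools index {bam_path}`"
            ) from exc
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                if stats is not None:
                    stats["skipped_nonprimary"] = stats.get("skipped_nonprimary", 0) + 1
                continue
            if aln.cigartuples is None:
                if stats is not None:
                    stats["skipped_no_cigar"] = stats.get("skipped_no_cigar", 0) + 1
                continue
            if aln.mapping_quality < min_mapq:
                if stats is not None:
                    stats["filtered"] = stats.get("filtered", 0) + 1
                continue
            yield _features_from_alignment(aln)


# -------------------------------------------------------------- assignment


def _nearest_cluster(clusters, position: int, window: int, strand: str):
    hits = [c for c in clusters if c.contains(position, window)]
    if not hits:
        return None
    best = min(abs(position - c.representative) for c in hits)
    tied = [c for c in hits if abs(position - c.representative) == best]
    if len(tied) > 1:  # tie -> 5'-most in transcriptional direction
        key = (lambda c: c.representative) if strand == "+" else (lambda c: -c.representative)
        tied.sort(key=key)
    return tied[0]


def assign_read(
    features: ReadFeatures,
    db: IsoformDatabase,
    index: GeneIndex | None = None,
    tss_window: int | None = None,
    tes_window: int | None = None,
    ignore_strand: bool = False,
) -> ReadAssignment:
    """Assign one read to a (gene, TSS cluster, TES cluster) triple.

    A read is ``full_length`` when its 5' end lies within the assignment
    window of a TSS cluster and its 3' end within that of a TES cluster of
    one and the same gene; among multiple matching clusters the nearest
    representative wins.  Reads satisfying this in more than one gene are
    ``ambiguous_gene``.
    """
    if index is None:
        index = GeneIndex(db)
    tw = db.tss_window if tss_window is None else tss_window
    ew = db.tes_window if tes_window is None else tes_window
    strand = None if ignore_strand else features.aln_strand
    candidates = index.overlapping(features.contig, strand, features.start, features.end)
    if not candidates:
        return ReadAssignment(features.read_id, status="unassigned")
    full: list[tuple[Gene, str, str]] = []
    any_tss = False
    for gid in candidates:
        g = db.genes[gid]
        # orient the span per gene strand (equals the alignment's own 5'/3'
        # whenever strands are required to match)
        five, three = (
            (features.start, features.end) if g.strand == "+"
            else (features.end, features.start)
        )
        tss = _nearest_cluster(g.tss, five, tw, g.strand)
        if tss is not None:
            any_tss = True
        tes = _nearest_cluster(g.tes, three, ew, g.strand)
        if tss is not None and tes is not None:
            full.append((g, tss.cluster_id, tes.cluster_id))
    if len(full) == 1:
        g, tss_id, tes_id = full[0]
        return ReadAssignment(features.read_id, g.gene_id, tss_id, tes_id, "full_length")
    if len(full) > 1:
        return ReadAssignment(features.read_id, status="ambiguous_gene")
    return ReadAssignment(
        features.read_id, status="no_tes" if any_tss else "no_tss"
    )


def count_links(
    bam_path: str | Path,
    db: IsoformDatabase,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    tss_window: int | None = None,
    tes_window: int | None = None,
    ignore_strand: bool = False,
) -> LinkCounts:
    """Count full-length reads into per-gene TSS x TES tables.

    Matrices cover every cluster combination of the database (zero-filled);
    read statuses partition all scanned primary alignments.
    """
    counts = LinkCounts()
    _init_matrices(counts, db)
    index = GeneIndex(db)
    totals = {s: 0 for s in STATUS_ORDER}
    totals["scanned"] = 0
    stats: dict[str, int] = {}
    for feats in extract_read_features(bam_path, min_mapq=min_mapq, stats=stats):
        totals["scanned"] += 1
        a = assign_read(
            feats, db, index,
            tss_window=tss_window, tes_window=tes_window,
            ignore_strand=ignore_strand,
        )
        counts.assignments.append(a)
        totals[a.status] += 1
        if a.status == "full_length":
            gid = a.gene_id
            i = counts.tss_ids[gid].index(a.tss_id)
            j = counts.tes_ids[gid].index(a.tes_id)
            counts.matrices[gid][i, j] += 1
    n_filtered = stats.get("filtered", 0)
    totals["filtered"] = n_filtered
    totals["scanned"] += n_filtered
    totals.update({k: v for k, v in stats.items() if k.startswith("skipped")})
    counts.totals = totals
    if totals["full_length"] == 0:
        logger.warning("no full-length reads found in %s", bam_path)
    return counts


def write_read_assignments(counts: LinkCounts, path: str | Path) -> None:
    """Write per-read assignments (BAM order) as TSV."""
    counts.assignment_frame().to_csv(path, sep="\t", index=False)


def filter_bam(
    bam_path: str | Path, counts: LinkCounts, out_path: str | Path
) -> int:
    """Write the full-length reads of ``counts`` to a sorted, indexed BAM."""
    keep = {a.read_id for a in counts.assignments if a.status == "full_length"}
    out_path = Path(out_path)
    tmp = out_path.with_suffix(".unsorted.bam")
    n = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        with pysam.AlignmentFile(str(tmp), "wb", template=bam) as out:
            for aln in bam.fetch(until_eof=True):
                if aln.is_secondary or aln.is_supplementary or aln.is_unmapped:
                    continue
                if aln.query_name in keep:
                    out.write(aln)
                    n += 1
    pysam.sort("-o", str(out_path), str(tmp))
    tmp.unlink()
    pysam.index(str(out_path))
    return n


def check_conservation(counts: LinkCounts) -> None:
    """Assert that statuses partition all scanned reads."""
    t = counts.totals
    parts = sum(t.get(s, 0) for s in STATUS_ORDER)
    if parts != t.get("scanned", 0):
        raise ConsistencyError(
            f"status tallies {parts} do not partition scanned reads {t.get('scanned')}"
        )
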