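"""Build a 5'-3' isoform database from a reference annotation.

A gene's transcripts are reduced to their strand-aware 5' (TSS) and 3'
(TES) positions.  Positions of each kind are clustered per gene with
single-linkage merging (consecutive gap <= window), and every TSS cluster
is paired with every TES cluster lying 3' of it, giving the set of
candidate 5'-3' isoforms against which full-length reads are counted.

Coordinates are 0-based half-open internally; TSS/TES positions are stored
as genomic boundary coordinates (a '+' TSS is an interval start, a '+' TES
an exclusive interval end, and vice versa on '-').
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr
from intervaltree import IntervalTree

from .errors import (
    DataError,
    EmptyDatabaseError,
    ParseError,
    UsageError,
)

logger = logging.getLogger(__name__)

DEFAULT_TSS_WINDOW = 50
DEFAULT_TES_WINDOW = 150

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(
                f"empty or inverted interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise DataError(f"unstranded interval {self.contig}:{self.start}-{self.end}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class ExonRecord:
    interval: GenomicInterval
    gene_id: str
    transcript_id: str
    gene_biotype: str


@dataclass
class EndCluster:
    """A cluster of transcript 5' or 3' end positions within one gene.

    ``representative`` is the modal member position (ties broken 5'-most in
    transcriptional direction); reads are assigned to the cluster when their
    end lies within ``representative +/- window``.
    """

    gene_id: str
    cluster_id: str
    kind: str  # "TSS" or "TES"
    contig: str
    strand: str
    representative: int
    window: int
    member_positions: list[int] = field(default_factory=list)

    def contains(self, position: int, window: int | None = None) -> bool:
        w = self.window if window is None else window
        return abs(position - self.representative) <= w

    @property
    def window_interval(self) -> tuple[int, int]:
        return (self.representative - self.window, self.representative + self.window)


@dataclass(frozen=True)
class IsoformPair:
    gene_id: str
    tss_id: str
    tes_id: str


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    tss: list[EndCluster] = field(default_factory=list)
    tes: list[EndCluster] = field(default_factory=list)
    pairs: list[IsoformPair] = field(default_factory=list)

    def clusters(self, kind: str) -> list[EndCluster]:
        if kind == "TSS":
            return self.tss
        if kind == "TES":
            return self.tes
        raise UsageError(f"unknown end kind {kind!r}")


@dataclass
class IsoformDatabase:
    """Per-gene TSS/TES clusters and their candidate 5'-3' pairings."""

    genes: dict[str, Gene]
    tss_window: int = DEFAULT_TSS_WINDOW
    tes_window: int = DEFAULT_TES_WINDOW
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def n_pairs(self) -> int:
        return sum(len(g.pairs) for g in self.genes.values())

    # ---------------------------------------------------------------- IO

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        crows, prows = [], []
        for g in self.genes.values():
            for cl in g.tss + g.tes:
                crows.append(
                    dict(
                        gene_id=g.gene_id,
                        cluster_id=cl.cluster_id,
                        kind=cl.kind,
                        contig=cl.contig,
                        strand=cl.strand,
                        representative=cl.representative,
                        window=cl.window,
                        members=",".join(map(str, cl.member_positions)),
                        gene_start=g.start,
                        gene_end=g.end,
                    )
                )
            for p in g.pairs:
                prows.append(dict(gene_id=p.gene_id, tss_id=p.tss_id, tes_id=p.tes_id))
        pd.DataFrame(
            crows,
            columns=[
                "gene_id", "cluster_id", "kind", "contig", "strand",
                "representative", "window", "members", "gene_start", "gene_end",
            ],
        ).to_csv(directory / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame(prows, columns=["gene_id", "tss_id", "tes_id"]).to_csv(
            directory / "pairs.tsv", sep="\t", index=False
        )
        (directory / "params.json").write_text(
            json.dumps(
                dict(
                    tss_window=self.tss_window,
                    tes_window=self.tes_window,
                    provenance=self.provenance,
                ),
                indent=2,
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "IsoformDatabase":
        directory = Path(directory)
        params = json.loads((directory / "params.json").read_text())
        clusters = pd.read_csv(directory / "clusters.tsv", sep="\t")
        pairs = pd.read_csv(directory / "pairs.tsv", sep="\t")
        genes: dict[str, Gene] = {}
        for _, row in clusters.iterrows():
            g = genes.get(row.gene_id)
            if g is None:
                g = Gene(
                    gene_id=row.gene_id,
                    contig=str(row.contig),
                    strand=row.strand,
                    start=int(row.gene_start),
                    end=int(row.gene_end),
                )
                genes[row.gene_id] = g
            cl = EndCluster(
                gene_id=row.gene_id,
                cluster_id=row.cluster_id,
                kind=row.kind,
                contig=str(row.contig),
                strand=row.strand,
                representative=int(row.representative),
                window=int(row.window),
                member_positions=[int(x) for x in str(row.members).split(",")],
            )
            g.clusters(row.kind).append(cl)
        for _, row in pairs.iterrows():
            genes[row.gene_id].pairs.append(
                IsoformPair(row.gene_id, row.tss_id, row.tes_id)
            )
        return cls(
            genes=genes,
            tss_window=int(params["tss_window"]),
            tes_window=int(params["tes_window"]),
            provenance=list(params.get("provenance", [])),
        )

    def to_gtf(self, path: str | Path) -> None:
        """Emit one single-exon transcript per 5'-3' pair (cluster
        representatives as ends), for browser inspection and round-tripping."""
        lines = []
        for g in sorted(self.genes.values(), key=lambda g: (g.contig, g.start)):
            reps = {c.cluster_id: c.representative for c in g.tss + g.tes}
            for p in g.pairs:
                t, e = reps[p.tss_id], reps[p.tes_id]
                start, end = (t, e) if g.strand == "+" else (e, t)
                tid = f"{p.tss_id}|{p.tes_id}".replace(":", ".")
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                    f'gene_biotype "protein_coding";'
                )
                lines.append(
                    f"{g.contig}\tisocouple\texon\t{start + 1}\t{end}\t.\t"
                    f"{g.strand}\t.\t{attrs}"
                )
        Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ parsing


def _first_malformed_line(gtf_path: str | Path) -> int | None:
    with open(gtf_path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                return i
    return None


def parse_annotation(
    gtf_path: str | Path, biotype_filter: str | None = "protein_coding"
) -> list[ExonRecord]:
    """Read exon records from a GTF, optionally keeping one gene biotype.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    Unstranded exon rows are dropped (with a warning); an empty result after
    filtering raises :class:`EmptyDatabaseError`.
    """
    try:
        df = pr.read_gtf(str(gtf_path)).df
    except Exception as exc:  # pyranges raises various types on bad input
        bad = _first_malformed_line(gtf_path)
        where = f" at line {bad}" if bad is not None else ""
        raise ParseError(f"malformed GTF {gtf_path}{where}: {exc}") from exc
    if df.empty:
        raise EmptyDatabaseError(f"no records in {gtf_path}")
    df = df[df.Feature == "exon"]
    if "gene_biotype" not in df.columns:
        logger.warning(
            "%s has no gene_biotype attribute; keeping all genes", gtf_path
        )
    elif biotype_filter is not None:
        df = df[df.gene_biotype == biotype_filter]
    n_unstranded = int((~df.Strand.isin(STRANDS)).sum())
    if n_unstranded:
        logger.warning("dropping %d unstranded exon rows", n_unstranded)
        df = df[df.Strand.isin(STRANDS)]
    if df.empty:
        raise EmptyDatabaseError(
            f"no exons left in {gtf_path} after filtering "
            f"(biotype_filter={biotype_filter!r})"
        )
    if "transcript_id" not in df.columns or df.transcript_id.isna().any():
        raise ParseError(f"{gtf_path}: exon rows without transcript_id")
    records = [
        ExonRecord(
            interval=GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End), r.Strand),
            gene_id=str(r.gene_id),
            transcript_id=str(r.transcript_id),
            gene_biotype=str(getattr(r, "gene_biotype", "")),
        )
        for r in df.itertuples(index=False)
    ]
    return records


def transcript_ends(
    exons: Iterable[ExonRecord],
) -> dict[str, tuple[str, str, str, int, int]]:
    """Per transcript: (gene_id, contig, strand, tss_position, tes_position).

    On '+' the TSS is the minimal exon start and the TES the maximal exon
    end; on '-' the roles swap.  Mixed strands or contigs within one
    transcript raise :class:`DataError`.
    """
    out: dict[str, tuple[str, str, str, int, int]] = {}
    by_tx: dict[str, list[ExonRecord]] = {}
    for ex in exons:
        by_tx.setdefault(ex.transcript_id, []).append(ex)
    for tid, exs in by_tx.items():
        strands = {e.interval.strand for e in exs}
        contigs = {e.interval.contig for e in exs}
        if len(strands) > 1 or len(contigs) > 1:
            raise DataError(f"transcript {tid} spans multiple strands/contigs")
        strand = strands.pop()
        lo = min(e.interval.start for e in exs)
        hi = max(e.interval.end for e in exs)
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        out[tid] = (exs[0].gene_id, contigs.pop(), strand, tss, tes)
    return out


# --------------------------------------------------------------- clustering


def cluster_positions(
    positions: Sequence[int], window: int, strand: str = "+"
) -> list[tuple[list[int], int]]:
    """Single-linkage clustering of 1-D positions.

    Sorted positions are merged while the gap between consecutive distinct
    values is <= ``window`` (so chains can span more than ``window``).
    Returns ``(members, representative)`` per cluster in genomic order;
    the representative is the modal member, ties broken 5'-most in
    transcriptional direction.
    """
    if window < 0:
        raise UsageError("window must be >= 0")
    pos = sorted(positions)
    if not pos:
        return []
    clusters: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out = []
    for members in clusters:
        counts: dict[int, int] = {}
        for m in members:
            counts[m] = counts.get(m, 0) + 1
        best = max(counts.values())
        modal = [m for m, c in counts.items() if c == best]
        rep = min(modal) if strand == "+" else max(modal)
        out.append((members, rep))
    return out


def _enumerate_pairs(gene: Gene) -> list[IsoformPair]:
    pairs = []
    for t in gene.tss:
        for e in gene.tes:
            if gene.strand == "+":
                ok = t.representative < e.representative
            else:
                ok = t.representative > e.representative
            if ok:
                pairs.append(IsoformPair(gene.gene_id, t.cluster_id, e.cluster_id))
    return pairs


def _number_clusters(gene: Gene) -> None:
    """Assign cluster ids ordered 5'->3' in transcriptional direction."""
    rev = gene.strand == "-"
    for kind, lst in (("TSS", gene.tss), ("TES", gene.tes)):
        lst.sort(key=lambda c: c.representative, reverse=rev)
        for i, cl in enumerate(lst, start=1):
            cl.cluster_id = f"{gene.gene_id}:{kind}{i}"


def prepare_isoform_database(
    exons: Iterable[ExonRecord],
    tss_window: int = DEFAULT_TSS_WINDOW,
    tes_window: int = DEFAULT_TES_WINDOW,
    provenance: str = "annotation",
) -> IsoformDatabase:
    """Cluster transcript ends per gene and enumerate candidate 5'-3' pairs."""
    if tss_window < 0 or tes_window < 0:
        raise UsageError("clustering windows must be >= 0")
    exons = list(exons)
    if not exons:
        raise EmptyDatabaseError("no exon records supplied")
    ends = transcript_ends(exons)
    span: dict[str, list[int]] = {}
    meta: dict[str, tuple[str, str]] = {}
    tss_pos: dict[str, list[int]] = {}
    tes_pos: dict[str, list[int]] = {}
    for ex in exons:
        s = span.setdefault(ex.gene_id, [ex.interval.start, ex.interval.end])
        s[0] = min(s[0], ex.interval.start)
        s[1] = max(s[1], ex.interval.end)
        meta[ex.gene_id] = (ex.interval.contig, ex.interval.strand)
    for gene_id, contig, strand, tss, tes in ends.values():
        tss_pos.setdefault(gene_id, []).append(tss)
        tes_pos.setdefault(gene_id, []).append(tes)

    genes: dict[str, Gene] = {}
    for gene_id in sorted(meta):
        contig, strand = meta[gene_id]
        if gene_id not in tss_pos:
            logger.warning("gene %s has no transcripts with exons; skipped", gene_id)
            continue
        g = Gene(gene_id, contig, strand, span[gene_id][0], span[gene_id][1])
        for members, rep in cluster_positions(tss_pos[gene_id], tss_window, strand):
            g.tss.append(
                EndCluster(gene_id, "", "TSS", contig, strand, rep, tss_window, members)
            )
        for members, rep in cluster_positions(tes_pos[gene_id], tes_window, strand):
            g.tes.append(
                EndCluster(gene_id, "", "TES", contig, strand, rep, tes_window, members)
            )
        _number_clusters(g)
        g.pairs = _enumerate_pairs(g)
        genes[gene_id] = g
    return IsoformDatabase(
        genes=genes,
        tss_window=tss_window,
        tes_window=tes_window,
        provenance=[provenance],
    )


# --------------------------------------------------- external end databases


@dataclass(frozen=True)
class ExternalEnd:
    interval: GenomicInterval
    kind: str  # "TSS" or "TES"

    def position(self) -> int:
        """Boundary coordinate of the end, matching transcript_ends()."""
        iv = self.interval
        if self.kind == "TSS":
            return iv.start if iv.strand == "+" else iv.end
        return iv.end if iv.strand == "+" else iv.start


def read_bed_ends(path: str | Path, kind: str) -> list[ExternalEnd]:
    """Read BED6 records (e.g. EPD promoters) as external TSS/TES features."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["contig", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
    except Exception as exc:
        raise ParseError(f"malformed BED {path}: {exc}") from exc
    return [
        ExternalEnd(
            GenomicInterval(str(r.contig), int(r.start), int(r.end), str(r.strand)),
            kind,
        )
        for r in df.itertuples(index=False)
        if r.strand in STRANDS
    ]


def read_gff_ends(path: str | Path, kind: str) -> list[ExternalEnd]:
    try:
        df = pr.read_gff3(str(path)).df
    except Exception:
        try:
            df = pr.read_gtf(str(path)).df
        except Exception as exc:
            raise ParseError(f"malformed GFF {path}: {exc}") from exc
    return [
        ExternalEnd(
            GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End), r.Strand),
            kind,
        )
        for r in df.itertuples(index=False)
        if r.Strand in STRANDS
    ]


def add_end_database(
    db: IsoformDatabase,
    external: Iterable[ExternalEnd],
    kind: str,
    window: int | None = None,
) -> IsoformDatabase:
    """Merge an external TSS or TES database into the isoform database.

    Each external end is assigned to every gene whose (window-extended)
    span it overlaps on the matching strand.  Ends within ``window`` of an
    existing same-kind cluster are absorbed as members (representative
    unchanged); the rest found new clusters and the pair cross-product is
    re-enumerated.  Unassignable records are counted and logged.
    """
    if kind not in ("TSS", "TES"):
        raise UsageError(f"kind must be TSS or TES, got {kind!r}")
    if window is None:
        window = db.tss_window if kind == "TSS" else db.tes_window
    if window < 0:
        raise UsageError("window must be >= 0")

    new = IsoformDatabase(
        genes={
            gid: Gene(
                g.gene_id, g.contig, g.strand, g.start, g.end,
                [replace(c, member_positions=list(c.member_positions)) for c in g.tss],
                [replace(c, member_positions=list(c.member_positions)) for c in g.tes],
                list(g.pairs),
            )
            for gid, g in db.genes.items()
        },
        tss_window=db.tss_window,
        tes_window=db.tes_window,
        provenance=list(db.provenance) + [f"external_{kind.lower()}"],
    )

    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in new.genes.values():
        trees.setdefault((g.contig, g.strand), IntervalTree()).addi(
            g.start - window, g.end + window, g.gene_id
        )

    n_unassigned = 0
    touched: set[str] = set()
    for rec in external:
        if rec.kind != kind:
            raise UsageError(
                f"external record kind {rec.kind!r} does not match requested {kind!r}"
            )
        pos = rec.position()
        tree = trees.get((rec.interval.contig, rec.interval.strand))
        hits = tree[pos] if tree is not None else set()
        if not hits:
            n_unassigned += 1
            continue
        for hit in hits:
            g = new.genes[hit.data]
            lst = g.clusters(kind)
            near = [c for c in lst if c.contains(pos, window)]
            if near:
                best = min(near, key=lambda c: abs(pos - c.representative))
                best.member_positions.append(pos)
            else:
                lst.append(
                    EndCluster(g.gene_id, "", kind, g.contig, g.strand, pos, window, [pos])
                )
                touched.add(g.gene_id)
    for gid in touched:
        g = new.genes[gid]
        _number_clusters(g)
        g.pairs = _enumerate_pairs(g)
    if n_unassigned:
        logger.warning(
            "%d external %s records overlapped no gene and were skipped",
            n_unassigned, kind,
        )
    return new


class GeneIndex:
    """Interval index of gene spans for read -> gene candidate lookup."""

    def __init__(self, db: IsoformDatabase) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in db.genes.values():
            self._trees.setdefault((g.contig, g.strand), IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )

    def overlapping(
        self, contig: str, strand: str | None, start: int, end: int
    ) -> list[str]:
        keys = (
            [(contig, strand)] if strand is not None
            else [(contig, "+"), (contig, "-")]
        )
        out: list[str] = []
        for key in keys:
            tree = self._trees.get(key)
            if tree is not None:
                out.extend(iv.data for iv in tree.overlap(start, end))
        return sorted(out)
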