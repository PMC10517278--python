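"""Exon-junction couplings with TSS/TES usage from corrected long reads.

A reference junction set is built from annotation introns, optionally
augmented with short-read junctions (STAR ``SJ.out.tab``) supported by at
least ``min_jcounts`` uniquely mapping reads.  Long-read intron chains are
corrected against this reference (each intron snapped to the unique
reference junction within ``tol`` nt on both boundaries), full-length reads
are retained, and per gene each junction's inclusion/exclusion is tabulated
against TSS (and TES) cluster usage and tested for independence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import ExonRecord, GeneIndex, IsoformDatabase
from .errors import EmptyDatabaseError, ParseError, UsageError
from .reads import DEFAULT_MIN_MAPQ, assign_read, extract_read_features
from .stats import (
    DEFAULT_ALPHA,
    DEFAULT_B,
    DEFAULT_MIN_READS,
    DEFAULT_RESIDUAL_CUTOFF,
    bh_adjust,
    chisq_mc_test,
    pearson_residuals,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_JCOUNTS = 2
DEFAULT_TOL = 10

_SJ_COLUMNS = [
    "contig", "start", "end", "strand_code", "motif",
    "annotated", "n_unique", "n_multi", "max_overhang",
]
_STRAND_CODE = {1: "+", 2: "-"}


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction; the intron span is 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str
    support: str  # "annotation", "short_read" or "both"
    short_read_count: int = 0

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.strand)


class JunctionDB:
    """Reference junction set with per-contig lookup by boundary tolerance."""

    def __init__(self, records: Iterable[JunctionRecord], params: dict | None = None):
        self.records: list[JunctionRecord] = sorted(
            records, key=lambda r: (r.contig, r.start, r.end, r.strand)
        )
        self.params = params or {}
        self._by_key = {r.key: r for r in self.records}
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[JunctionRecord]]] = {}
        grouped: dict[tuple[str, str], list[JunctionRecord]] = {}
        for r in self.records:
            grouped.setdefault((r.contig, r.strand), []).append(r)
        for key, recs in grouped.items():
            starts = np.array([r.start for r in recs])
            ends = np.array([r.end for r in recs])
            self._index[key] = (starts, ends, recs)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key) -> bool:
        return key in self._by_key

    def candidates(
        self, contig: str, strand: str, start: int, end: int, tol: int
    ) -> list[JunctionRecord]:
        """Reference junctions with both boundaries within ``tol``."""
        entry = self._index.get((contig, strand))
        if entry is None:
            return []
        starts, ends, recs = entry
        mask = (np.abs(starts - start) <= tol) & (np.abs(ends - end) <= tol)
        return [recs[i] for i in np.nonzero(mask)[0]]

    def in_span(
        self, contig: str, strand: str, start: int, end: int
    ) -> list[JunctionRecord]:
        entry = self._index.get((contig, strand))
        if entry is None:
            return []
        starts, ends, recs = entry
        mask = (starts >= start) & (ends <= end)
        return [recs[i] for i in np.nonzero(mask)[0]]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                dict(contig=r.contig, start=r.start, end=r.end, strand=r.strand,
                     support=r.support, short_read_count=r.short_read_count)
                for r in self.records
            ],
            columns=["contig", "start", "end", "strand", "support", "short_read_count"],
        ).to_csv(directory / "junctions.tsv", sep="\t", index=False)
        (directory / "params.json").write_text(json.dumps(self.params, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "JunctionDB":
        directory = Path(directory)
        df = pd.read_csv(directory / "junctions.tsv", sep="\t")
        recs = [
            JunctionRecord(str(r.contig), int(r.start), int(r.end), r.strand,
                           r.support, int(r.short_read_count))
            for r in df.itertuples(index=False)
        ]
        params = json.loads((directory / "params.json").read_text())
        return cls(recs, params)


# ------------------------------------------------------------------ builders


def parse_star_sj(
    path: str | Path, min_jcounts: int = DEFAULT_MIN_JCOUNTS
) -> list[JunctionRecord]:
    """Read STAR ``SJ.out.tab``, keeping stranded junctions with enough
    unique-mapper support.

    STAR intron coordinates are 1-based inclusive; they are converted to
    0-based half-open.  Strand code 0 (undefined) rows are dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read SJ file {path}: {exc}") from exc
    if df.shape[1] != 9:
        raise ParseError(
            f"{path}: expected 9 columns (STAR SJ.out.tab), found {df.shape[1]}"
        )
    df.columns = _SJ_COLUMNS
    n_unstranded = int((df.strand_code == 0).sum())
    if n_unstranded:
        logger.warning("dropping %d junctions with undefined strand", n_unstranded)
    df = df[(df.strand_code.isin((1, 2))) & (df.n_unique >= min_jcounts)]
    return [
        JunctionRecord(
            contig=str(r.contig),
            start=int(r.start) - 1,
            end=int(r.end),
            strand=_STRAND_CODE[int(r.strand_code)],
            support="short_read",
            short_read_count=int(r.n_unique),
        )
        for r in df.itertuples(index=False)
    ]


def annotation_junctions(exons: Iterable[ExonRecord]) -> list[JunctionRecord]:
    """Introns between consecutive exons of each annotated transcript."""
    by_tx: dict[str, list[ExonRecord]] = {}
    for ex in exons:
        by_tx.setdefault(ex.transcript_id, []).append(ex)
    seen: dict[tuple, JunctionRecord] = {}
    for exs in by_tx.values():
        exs = sorted(exs, key=lambda e: e.interval.start)
        for a, b in zip(exs, exs[1:]):
            if b.interval.start <= a.interval.end:
                continue  # abutting or overlapping exons: no intron
            rec = JunctionRecord(
                a.interval.contig, a.interval.end, b.interval.start,
                a.interval.strand, "annotation",
            )
            seen.setdefault(rec.key, rec)
    return list(seen.values())


def create_reference_junctions(
    short_sj: str | Path | Sequence[JunctionRecord] | None,
    annotation_exons: Iterable[ExonRecord],
    min_jcounts: int = DEFAULT_MIN_JCOUNTS,
    type: str = "short",
) -> JunctionDB:
    """Build the reference junction set.

    ``type="short"`` unions annotation introns with filtered short-read
    junctions (support flag ``both`` where duplicated); ``type="annotation"``
    ignores the short-read input.
    """
    if type not in ("short", "annotation"):
        raise UsageError(f"type must be 'short' or 'annotation', got {type!r}")
    annot = {r.key: r for r in annotation_junctions(annotation_exons)}
    merged: dict[tuple, JunctionRecord] = dict(annot)
    if type == "short" and short_sj is not None:
        if isinstance(short_sj, (str, Path)):
            short = parse_star_sj(short_sj, min_jcounts=min_jcounts)
        else:
            short = [r for r in short_sj if r.short_read_count >= min_jcounts]
        for r in short:
            if r.key in merged:
                merged[r.key] = JunctionRecord(
                    r.contig, r.start, r.end, r.strand, "both", r.short_read_count
                )
            else:
                merged[r.key] = r
    if not merged:
        raise EmptyDatabaseError("reference junction set is empty")
    return JunctionDB(
        merged.values(), params=dict(min_jcounts=min_jcounts, type=type)
    )


# ----------------------------------------------------------------- correction


@dataclass
class CorrectionResult:
    status: str  # "exact", "snapped" or "rejected"
    chain: list[tuple[int, int]] | None
    reason: str = ""


def correct_junctions(
    introns: Sequence[tuple[int, int]],
    db: JunctionDB,
    contig: str,
    strand: str,
    tol: int = DEFAULT_TOL,
    snap_closest: bool = False,
) -> CorrectionResult:
    """Snap a read's intron chain onto the reference junction set.

    Each intron must match exactly one reference junction with both
    boundaries within ``tol``; exact matches pass through.  Zero candidates
    reject the read (``novel_junction``); more than one rejects it too
    (``ambiguous_junction``) unless ``snap_closest`` picks the nearest.
    """
    if tol < 0:
        raise UsageError("tol must be >= 0")
    chain: list[tuple[int, int]] = []
    any_snapped = False
    for (s, e) in introns:
        if (contig, s, e, strand) in db:
            chain.append((s, e))
            continue
        cands = db.candidates(contig, strand, s, e, tol)
        if not cands:
            return CorrectionResult("rejected", None, "novel_junction")
        if len(cands) > 1:
            if not snap_closest:
                return CorrectionResult("rejected", None, "ambiguous_junction")
            cands.sort(key=lambda r: (abs(r.start - s) + abs(r.end - e), r.start))
            cands = cands[:1]
        chain.append((cands[0].start, cands[0].end))
        any_snapped = True
    for (a, b), (c, d) in zip(chain, chain[1:]):
        if c < b:
            return CorrectionResult("rejected", None, "disordered_chain")
    return CorrectionResult("snapped" if any_snapped else "exact", chain)


# ------------------------------------------------------------- link counting


@dataclass
class ExonLinkCounts:
    """Per-gene junction inclusion/exclusion counts split by TSS/TES usage.

    ``tables[gene][junction_key][axis]`` holds two dicts (inclusion,
    exclusion) keyed by cluster id.
    """

    tables: dict[str, dict[tuple, dict[str, tuple[dict, dict]]]] = field(
        default_factory=dict
    )
    cluster_ids: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    reads: list[dict] = field(default_factory=list)
    correction_stats: dict[str, int] = field(default_factory=dict)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.tables):
            for jkey in sorted(self.tables[gid]):
                contig, js, je, strand = jkey
                for axis in ("TSS", "TES"):
                    inc, exc = self.tables[gid][jkey][axis]
                    for cid in self.cluster_ids[gid][axis]:
                        rows.append(
                            (gid, contig, js, je, strand, axis, cid,
                             inc.get(cid, 0), exc.get(cid, 0))
                        )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "contig", "junction_start", "junction_end",
                     "strand", "axis", "cluster_id", "inclusion", "exclusion"],
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(
            directory / "exon_link_counts.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.reads).to_csv(
            directory / "corrected_reads.tsv", sep="\t", index=False
        )
        (directory / "correction_stats.json").write_text(
            json.dumps(self.correction_stats, indent=2)
        )


def read_to_junctions(
    bam_path: str | Path,
    jdb: JunctionDB,
    isoform_db: IsoformDatabase,
    tol: int = DEFAULT_TOL,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    snap_closest: bool = False,
    tss_window: int | None = None,
    tes_window: int | None = None,
) -> ExonLinkCounts:
    """Corrected junction x TSS/TES inclusion tables from full-length reads.

    A read contributes *inclusion* for every reference junction in its
    corrected chain, and *exclusion* for a junction whose intron interval
    lies inside the read's aligned span but is absent from the chain (the
    read used another splice form there, or retained the intron).  Junctions
    outside the aligned span contribute neither.
    """
    out = ExonLinkCounts()
    for gid, g in isoform_db.genes.items():
        out.cluster_ids[gid] = {
            "TSS": [c.cluster_id for c in g.tss],
            "TES": [c.cluster_id for c in g.tes],
        }
    index = GeneIndex(isoform_db)
    cstats = dict(exact=0, snapped=0, rejected=0, not_full_length=0)
    for feats in extract_read_features(bam_path, min_mapq=min_mapq):
        a = assign_read(
            feats, isoform_db, index, tss_window=tss_window, tes_window=tes_window
        )
        if a.status != "full_length":
            cstats["not_full_length"] += 1
            continue
        g = isoform_db.genes[a.gene_id]
        corr = correct_junctions(
            feats.introns, jdb, feats.contig, feats.aln_strand,
            tol=tol, snap_closest=snap_closest,
        )
        cstats[corr.status] += 1
        out.reads.append(
            dict(
                read_id=feats.read_id, gene_id=a.gene_id,
                tss_id=a.tss_id, tes_id=a.tes_id, status=corr.status,
                reason=corr.reason,
                chain=";".join(f"{s}-{e}" for s, e in (corr.chain or [])),
            )
        )
        if corr.status == "rejected":
            continue
        chain = set(corr.chain)
        gene_tables = out.tables.setdefault(a.gene_id, {})
        for rec in jdb.in_span(g.contig, g.strand, g.start, g.end):
            jkey = rec.key
            included = (rec.start, rec.end) in chain
            excluded = (
                not included
                and feats.start <= rec.start
                and rec.end <= feats.end
            )
            if not (included or excluded):
                continue
            axes = gene_tables.setdefault(
                jkey, {"TSS": ({}, {}), "TES": ({}, {})}
            )
            for axis, cid in (("TSS", a.tss_id), ("TES", a.tes_id)):
                inc, exc = axes[axis]
                d = inc if included else exc
                d[cid] = d.get(cid, 0) + 1
    out.correction_stats = cstats
    return out


# --------------------------------------------------------------- statistics


def calculate_exon_couplings(
    counts: ExonLinkCounts,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    residual_cutoff: float = DEFAULT_RESIDUAL_CUTOFF,
    min_reads: int = DEFAULT_MIN_READS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test each (gene, junction, axis) 2xK inclusion/exclusion table.

    Junctions need >= ``min_reads`` spanning reads, both a non-empty
    inclusion and exclusion row, and >= 2 non-empty cluster columns; BH
    adjustment runs across all tested (junction, axis) pairs.  Residuals
    reported per cluster are the Pearson residuals of the inclusion row.
    """
    units = []
    for gid in sorted(counts.tables):
        for jkey in sorted(counts.tables[gid]):
            for axis in ("TSS", "TES"):
                units.append((gid, jkey, axis))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(units)) if units else []
    rows = []
    for k, (gid, jkey, axis) in enumerate(units):
        cids = counts.cluster_ids[gid][axis]
        inc, exc = counts.tables[gid][jkey][axis]
        table = np.array(
            [[inc.get(c, 0) for c in cids], [exc.get(c, 0) for c in cids]],
            dtype=np.int64,
        )
        n = int(table.sum())
        tested = (
            n >= min_reads
            and (table.sum(axis=1) > 0).all()
            and (table.sum(axis=0) > 0).sum() >= 2
        )
        stat = p = np.nan
        res_str = ""
        if tested:
            stat, p = chisq_mc_test(
                table, B=B, seed=np.random.default_rng(children[k])
            )
            res = pearson_residuals(table)[0]  # inclusion row
            res_str = ";".join(f"{c}:{r:.4f}" for c, r in zip(cids, res))
        contig, js, je, strand = jkey
        rows.append(
            dict(
                gene_id=gid, contig=contig, junction_start=js, junction_end=je,
                strand=strand, axis=axis, n_reads=n, chisq_stat=stat,
                p_value=p, q_value=np.nan, tested=tested, residuals=res_str,
                coupled=False,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "contig", "junction_start", "junction_end", "strand",
                 "axis", "n_reads", "chisq_stat", "p_value", "q_value",
                 "tested", "residuals", "coupled"],
    )
    mask = df.tested.to_numpy(dtype=bool) if len(df) else np.array([], bool)
    if mask.any():
        df.loc[mask, "q_value"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
        max_abs = df.loc[mask, "residuals"].map(
            lambda s: max(abs(float(x.rsplit(":", 1)[1])) for x in s.split(";"))
        )
        df.loc[mask, "coupled"] = (df.loc[mask, "q_value"] <= alpha) & (
            max_abs >= residual_cutoff
        )
    return df


def residual_frame(results: pd.DataFrame) -> pd.DataFrame:
    """Explode the per-cluster inclusion residual strings into long format."""
    rows = []
    for r in results.itertuples(index=False):
        if not isinstance(r.residuals, str) or not r.residuals:
            continue
        for item in r.residuals.split(";"):
            cid, val = item.rsplit(":", 1)
            rows.append(
                (r.gene_id, r.junction_start, r.junction_end, r.axis, cid, float(val))
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "junction_start", "junction_end", "axis",
                 "cluster_id", "residual"],
    )
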