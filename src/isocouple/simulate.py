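"""Synthetic annotation and aligned-read fixtures with known coupling truth.

Genes are laid out without overlap on one contig, each with configurable
numbers of TSSs, TESs and internal (optionally skipped) exons.  Reads are
drawn per gene from a TSS x TES coupling matrix, junction inclusions are
sampled conditional on the TSS, and alignment-level noise is applied: a
bounded jitter on both read ends, 5' truncation past the TSS window, and a
bounded wobble on junction boundaries.  Reads are emitted as a sorted,
indexed BAM together with a per-read truth table, so every pipeline stage
can be checked against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import LayoutError, UsageError

DEFAULT_CONTIG = "chrS"


def independent_coupling(n_tss: int, n_tes: int) -> np.ndarray:
    """Conditional TES-given-TSS matrix under independence (uniform rows)."""
    return np.full((n_tss, n_tes), 1.0 / n_tes)


def biased_coupling(p: float = 0.75) -> np.ndarray:
    """2x2 coupling with odds ratio (p/(1-p))^2 (p=0.75 gives OR 9)."""
    return np.array([[p, 1 - p], [1 - p, p]])


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    ``coupling_matrices[g][i, j]`` is P(TES_j | TSS_i) for gene ``g`` (rows
    sum to 1); ``None`` means independence with uniform TES usage.
    ``inclusion_probs[g][i, k]`` is the probability that internal exon ``k``
    is included in a read starting at TSS_i; ``None`` means constitutive
    inclusion.  Spacings default to several times the assignment windows so
    cluster recovery is unambiguous.
    """

    n_genes: int = 10
    n_tss: int = 2
    n_tes: int = 2
    n_internal_exons: int = 2
    tss_spacing: int = 400
    tes_spacing: int = 600
    first_exon_len: int = 300
    last_exon_len: int = 300
    exon_len: int = 200
    intron_len: int = 500
    gene_gap: int = 2000
    contig: str = DEFAULT_CONTIG
    contig_length: int | None = None
    strands: str = "alternate"  # "alternate", "+" or "-"
    n_reads: int = 200
    end_jitter_sd: float = 10.0
    tss_window: int = 50
    tes_window: int = 150
    truncation_fraction: float = 0.2
    truncation_min_extra: int = 5
    truncation_max_extra: int = 200
    junction_noise: int = 3
    tss_probs: Sequence[float] | None = None
    coupling_matrices: list[np.ndarray] | None = None
    inclusion_probs: list[np.ndarray] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_tss < 1 or self.n_tes < 1:
            raise UsageError("n_genes, n_tss and n_tes must be >= 1")
        if self.first_exon_len <= self.tss_window + self.truncation_max_extra:
            raise LayoutError(
                "first_exon_len must exceed tss_window + truncation_max_extra "
                "so truncated 5' ends stay inside the first exon"
            )
        if self.junction_noise * 2 >= min(self.exon_len, self.intron_len):
            raise LayoutError("junction_noise too large for exon/intron lengths")
        if self.strands not in ("alternate", "+", "-"):
            raise UsageError("strands must be 'alternate', '+' or '-'")
        for name, mats, shape in (
            ("coupling_matrices", self.coupling_matrices, (self.n_tss, self.n_tes)),
            ("inclusion_probs", self.inclusion_probs,
             (self.n_tss, self.n_internal_exons)),
        ):
            if mats is None:
                continue
            if len(mats) != self.n_genes:
                raise UsageError(f"{name} must have one matrix per gene")
            for m in mats:
                m = np.asarray(m, dtype=float)
                if m.shape != shape:
                    raise UsageError(f"{name} entries must have shape {shape}")
                if (m < 0).any() or (m > 1).any():
                    raise UsageError(f"{name} entries must lie in [0, 1]")
        if self.coupling_matrices is not None:
            for m in self.coupling_matrices:
                if not np.allclose(np.asarray(m, float).sum(axis=1), 1.0):
                    raise UsageError("coupling matrix rows must sum to 1")


@dataclass
class GeneLayout:
    """One simulated gene in local (transcriptional) coordinates.

    Local boundary x maps to the genomic boundary ``offset + x`` on '+'
    and ``offset + length - x`` on '-'.
    """

    gene_id: str
    contig: str
    strand: str
    offset: int
    length: int
    tss_local: list[int]          # 5'->3', index 0 is TSS1
    tes_local: list[int]
    exon1_end: int
    internal_exons: list[tuple[int, int]]
    last_exon_start: int

    def to_genomic(self, boundary: int) -> int:
        if self.strand == "+":
            return self.offset + boundary
        return self.offset + self.length - boundary

    def interval_to_genomic(self, start: int, end: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.offset + start, self.offset + end
        return self.offset + self.length - end, self.offset + self.length - start

    def donors_acceptors(self) -> tuple[list[int], list[int]]:
        """Exon-end (donor) and exon-start (acceptor) local boundaries, in
        transcription order: exon 0 = first exon, exon m+1 = last exon."""
        donors = [self.exon1_end] + [e for _, e in self.internal_exons]
        acceptors = [s for s, _ in self.internal_exons] + [self.last_exon_start]
        return donors, acceptors

    def junction_local(self, a: int, b: int) -> tuple[int, int]:
        """Local intron span for splicing exon ``a`` to exon ``b`` (a < b)."""
        donors, acceptors = self.donors_acceptors()
        return donors[a], acceptors[b - 1]

    def all_junctions_local(self) -> list[tuple[int, int]]:
        m = len(self.internal_exons)
        return [
            self.junction_local(a, b)
            for a in range(m + 1)
            for b in range(a + 1, m + 2)
        ]

    def junction_genomic(self, a: int, b: int) -> tuple[int, int]:
        s, e = self.junction_local(a, b)
        return self.interval_to_genomic(s, e)

    def tss_id(self, i: int) -> str:
        return f"{self.gene_id}:TSS{i + 1}"

    def tes_id(self, j: int) -> str:
        return f"{self.gene_id}:TES{j + 1}"


def _build_layouts(config: SimConfig) -> list[GeneLayout]:
    config.validate()
    m = config.n_internal_exons
    tss_local = [i * config.tss_spacing for i in range(config.n_tss)]
    exon1_end = tss_local[-1] + config.first_exon_len
    internal = []
    cur = exon1_end
    for _ in range(m):
        s = cur + config.intron_len
        internal.append((s, s + config.exon_len))
        cur = s + config.exon_len
    last_start = cur + config.intron_len
    tes_local = [
        last_start + config.last_exon_len + j * config.tes_spacing
        for j in range(config.n_tes)
    ]
    length = tes_local[-1]
    layouts = []
    offset = 1000
    for g in range(config.n_genes):
        if config.strands == "alternate":
            strand = "+" if g % 2 == 0 else "-"
        else:
            strand = config.strands
        layouts.append(
            GeneLayout(
                gene_id=f"G{g + 1:03d}",
                contig=config.contig,
                strand=strand,
                offset=offset,
                length=length,
                tss_local=list(tss_local),
                tes_local=list(tes_local),
                exon1_end=exon1_end,
                internal_exons=list(internal),
                last_exon_start=last_start,
            )
        )
        offset += length + config.gene_gap
    total = offset + 1000
    if config.contig_length is not None and total > config.contig_length:
        raise LayoutError(
            f"layout needs {total} nt but contig_length is {config.contig_length}"
        )
    return layouts


def generate_annotation(
    config: SimConfig, gtf_path: str | Path
) -> list[GeneLayout]:
    """Write a GTF realizing every TSS x TES combination of each gene.

    Each transcript uses one TSS, one TES and all internal exons; skipped
    exon forms appear in reads (and in the short-read junction file), not in
    the annotation.  Byte-identical output for identical configs.
    """
    layouts = _build_layouts(config)
    lines = []
    for lay in layouts:
        for i in range(config.n_tss):
            for j in range(config.n_tes):
                tid = f"{lay.gene_id}.t{i + 1}_{j + 1}"
                exons_local = (
                    [(lay.tss_local[i], lay.exon1_end)]
                    + lay.internal_exons
                    + [(lay.last_exon_start, lay.tes_local[j])]
                )
                genomic = sorted(
                    lay.interval_to_genomic(s, e) for s, e in exons_local
                )
                for (s, e) in genomic:
                    attrs = (
                        f'gene_id "{lay.gene_id}"; transcript_id "{tid}"; '
                        f'gene_biotype "protein_coding";'
                    )
                    lines.append(
                        f"{lay.contig}\tisocouple_sim\texon\t{s + 1}\t{e}\t.\t"
                        f"{lay.strand}\t.\t{attrs}"
                    )
    Path(gtf_path).write_text("\n".join(lines) + "\n")
    return layouts


def _contig_length(layouts: list[GeneLayout], config: SimConfig) -> int:
    last = layouts[-1]
    return last.offset + last.length + config.gene_gap + 1000


def simulate_reads(
    config: SimConfig,
    layouts: list[GeneLayout],
    bam_path: str | Path,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Emit spliced alignments per the coupling model; return the truth table.

    Per read: (TSS, TES) sampled from the gene's coupling matrix, internal
    exon inclusions Bernoulli conditional on the TSS, end jitter truncated
    at half the respective window, 5' truncation past the TSS window with
    the configured probability, and bounded junction-boundary wobble.  The
    truth table records the noiseless junction chain in genomic coordinates.
    """
    config.validate()
    rng_children = np.random.SeedSequence(config.seed).spawn(len(layouts))
    jit5_cap = config.tss_window // 2
    jit3_cap = config.tes_window // 2
    m = config.n_internal_exons
    tss_probs = (
        np.full(config.n_tss, 1.0 / config.n_tss)
        if config.tss_probs is None
        else np.asarray(config.tss_probs, dtype=float)
    )
    records = []
    truth_rows = []
    for g, lay in enumerate(layouts):
        rng = np.random.default_rng(rng_children[g])
        coupling = (
            independent_coupling(config.n_tss, config.n_tes)
            if config.coupling_matrices is None
            else np.asarray(config.coupling_matrices[g], dtype=float)
        )
        incl = (
            np.ones((config.n_tss, m))
            if config.inclusion_probs is None
            else np.asarray(config.inclusion_probs[g], dtype=float)
        )
        for r in range(config.n_reads):
            i = int(rng.choice(config.n_tss, p=tss_probs))
            j = int(rng.choice(config.n_tes, p=coupling[i]))
            included = [k for k in range(m) if rng.random() < incl[i, k]]
            exon_seq = [0] + [k + 1 for k in included] + [m + 1]
            true_juncs = [
                lay.junction_local(a, b) for a, b in zip(exon_seq, exon_seq[1:])
            ]
            truncated = rng.random() < config.truncation_fraction
            if truncated:
                five = lay.tss_local[i] + config.tss_window + int(
                    rng.integers(config.truncation_min_extra,
                                 config.truncation_max_extra + 1)
                )
            else:
                d5 = int(np.clip(round(rng.normal(0, config.end_jitter_sd)),
                                 -jit5_cap, jit5_cap))
                five = lay.tss_local[i] + d5
            d3 = int(np.clip(round(rng.normal(0, config.end_jitter_sd)),
                             -jit3_cap, jit3_cap))
            three = lay.tes_local[j] + d3
            noisy = [
                (
                    s + int(rng.integers(-config.junction_noise,
                                         config.junction_noise + 1)),
                    e + int(rng.integers(-config.junction_noise,
                                         config.junction_noise + 1)),
                )
                for s, e in true_juncs
            ] if config.junction_noise > 0 else list(true_juncs)
            blocks_local = []
            cur = five
            for s, e in noisy:
                blocks_local.append((cur, s))
                cur = e
            blocks_local.append((cur, three))
            blocks = sorted(
                lay.interval_to_genomic(s, e) for s, e in blocks_local
            )
            read_id = f"{lay.gene_id}_r{r:05d}"
            records.append((lay.strand, blocks, read_id))
            chain_genomic = sorted(
                lay.interval_to_genomic(s, e) for s, e in true_juncs
            )
            truth_rows.append(
                dict(
                    read_id=read_id,
                    gene_id=lay.gene_id,
                    tss_id=lay.tss_id(i),
                    tes_id=lay.tes_id(j),
                    truncated=truncated,
                    chain=";".join(f"{s}-{e}" for s, e in chain_genomic),
                )
            )
    contig_len = _contig_length(layouts, config)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.contig, "LN": contig_len}],
    }
    records.sort(key=lambda t: t[1][0][0])
    bam_path = Path(bam_path)
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as out:
        for strand, blocks, read_id in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read_id
            a.flag = 16 if strand == "-" else 0
            a.reference_id = 0
            a.reference_start = blocks[0][0]
            a.mapping_quality = 60
            cig = []
            for k, (s, e) in enumerate(blocks):
                if k:
                    cig.append((3, s - blocks[k - 1][1]))  # N
                cig.append((0, e - s))  # M
            a.cigartuples = cig
            out.write(a)
    pysam.index(str(bam_path))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "gene_id", "tss_id", "tes_id", "truncated", "chain"],
    )
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def truth_tallies(truth: pd.DataFrame, full_length_only: bool = True) -> dict:
    """Per-gene TSS x TES count tables implied by the truth labels."""
    df = truth[~truth.truncated] if full_length_only else truth
    out = {}
    for gid, sub in df.groupby("gene_id"):
        out[gid] = (
            sub.groupby(["tss_id", "tes_id"]).size().unstack(fill_value=0)
        )
    return out


def write_star_sj(
    config: SimConfig,
    layouts: list[GeneLayout],
    path: str | Path,
    support: int = 50,
    decoys_per_gene: int = 0,
    decoy_count: int = 1,
    decoy_shift: int = 37,
) -> None:
    """Write the true junction set (all splice forms) as STAR SJ.out.tab.

    Decoy junctions, shifted copies of the first junction with
    ``decoy_count`` supporting reads, exercise the min_jcounts filter.
    """
    rows = []
    code = {"+": 1, "-": 2}
    for lay in layouts:
        juncs = sorted(
            lay.interval_to_genomic(s, e) for s, e in lay.all_junctions_local()
        )
        for (s, e) in juncs:
            rows.append((lay.contig, s + 1, e, code[lay.strand], 0, 1, support, 0, 30))
        for d in range(decoys_per_gene):
            s, e = juncs[0]
            shift = decoy_shift * (d + 1)
            rows.append(
                (lay.contig, s + shift + 1, e + shift, code[lay.strand],
                 0, 0, decoy_count, 0, 30)
            )
    rows.sort()
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def save_config(config: SimConfig, path: str | Path) -> None:
    d = asdict(config)
    for key in ("coupling_matrices", "inclusion_probs"):
        if d[key] is not None:
            d[key] = [np.asarray(m).tolist() for m in d[key]]
    if d["tss_probs"] is not None:
        d["tss_probs"] = list(map(float, d["tss_probs"]))
    Path(path).write_text(json.dumps(d, indent=2))
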