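from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

from isocouple.annotation import parse_annotation, prepare_isoform_database
from isocouple.simulate import (
    SimConfig,
    biased_coupling,
    generate_annotation,
    simulate_reads,
    write_star_sj,
)


def write_gtf(path: Path, rows) -> Path:
    """rows: (contig, start0, end0, strand, gene_id, transcript_id, biotype)."""
    lines = []
    for contig, s, e, strand, gid, tid, biotype in rows:
        attrs = (
            f'gene_id "{gid}"; transcript_id "{tid}"; gene_biotype "{biotype}";'
        )
        lines.append(f"{contig}\ttest\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}")
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class SimBundle:
    cfg: SimConfig
    layouts: list
    gtf: Path
    bam: Path
    sj: Path
    truth: "object"
    exons: list
    db: "object"


def build_bundle(directory: Path, cfg: SimConfig, sj_kwargs=None) -> SimBundle:
    directory.mkdir(parents=True, exist_ok=True)
    gtf = directory / "sim.gtf"
    bam = directory / "sim.bam"
    sj = directory / "SJ.out.tab"
    layouts = generate_annotation(cfg, gtf)
    truth = simulate_reads(cfg, layouts, bam, directory / "truth.tsv")
    write_star_sj(cfg, layouts, sj, **(sj_kwargs or {}))
    exons = parse_annotation(gtf)
    db = prepare_isoform_database(
        exons, tss_window=cfg.tss_window, tes_window=cfg.tes_window
    )
    return SimBundle(cfg, layouts, gtf, bam, sj, truth, exons, db)


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory) -> SimBundle:
    """Zero jitter/truncation/junction-noise cohort: counts must equal truth."""
    cfg = SimConfig(
        n_genes=4,
        n_reads=150,
        seed=101,
        end_jitter_sd=0.0,
        truncation_fraction=0.0,
        junction_noise=0,
        coupling_matrices=[biased_coupling(0.75)] * 4,
    )
    return build_bundle(tmp_path_factory.mktemp("noiseless"), cfg)


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory) -> SimBundle:
    """Default noise levels (jitter, 20% truncation, junction wobble)."""
    cfg = SimConfig(n_genes=6, n_reads=250, seed=42)
    return build_bundle(
        tmp_path_factory.mktemp("noisy"), cfg, sj_kwargs=dict(decoys_per_gene=1)
    )


@pytest.fixture()
def two_gene_gtf(tmp_path) -> Path:
    """One protein-coding gene (3 exons, 2 transcripts) + one lncRNA gene."""
    rows = [
        ("chr1", 100, 200, "+", "pcg1", "pcg1.t1", "protein_coding"),
        ("chr1", 500, 600, "+", "pcg1", "pcg1.t1", "protein_coding"),
        ("chr1", 900, 1100, "+", "pcg1", "pcg1.t2", "protein_coding"),
        ("chr1", 2000, 2100, "+", "lnc1", "lnc1.t1", "lncRNA"),
        ("chr1", 2500, 2600, "+", "lnc1", "lnc1.t1", "lncRNA"),
    ]
    return write_gtf(tmp_path / "two_gene.gtf", rows)
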