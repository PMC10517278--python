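"""Independence testing of TSS x TES tables and promoter-dominance calls.

For each gene with at least two TSS and two TES clusters, the observed
full-length counts are tested against the independence expectation
``E[i,j] = rowsum_i * colsum_j / total`` with a Monte-Carlo chi-squared
test: null tables share the observed margins (Patefield sampling) and

    p = (1 + #{simulated stat >= observed stat}) / (B + 1).

Gene-level p-values are Benjamini-Hochberg adjusted; a (TSS, TES) pair is
called *coupled* when its gene is significant and the cell's Pearson
residual (O - E)/sqrt(E) passes the cutoff.  Promoter dominance summarises,
per TES, each TSS's contribution fraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotation import IsoformDatabase
from .errors import ConsistencyError, DegenerateTableError, UsageError
from .reads import LinkCounts

logger = logging.getLogger(__name__)

DEFAULT_B = 2000
DEFAULT_ALPHA = 0.01
DEFAULT_RESIDUAL_CUTOFF = 0.5
DEFAULT_MIN_READS = 20
DEFAULT_DOMINANCE_THRESHOLD = 0.5


def expected_table(observed: np.ndarray) -> np.ndarray:
    """Independence expectation with the observed margins."""
    obs = np.asarray(observed, dtype=float)
    total = obs.sum()
    if total <= 0:
        raise DegenerateTableError("all-zero contingency table")
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total


def pearson_residuals(observed: np.ndarray) -> np.ndarray:
    """(O - E)/sqrt(E), zero where a margin is empty (E == 0)."""
    obs = np.asarray(observed, dtype=float)
    exp = expected_table(obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = (obs - exp) / np.sqrt(exp)
    return np.where(exp > 0, res, 0.0)


def _chisq_stat(obs: np.ndarray, exp: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - exp) ** 2 / exp
    return float(np.where(exp > 0, terms, 0.0).sum())


def chisq_mc_test(
    observed: np.ndarray,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    null: str = "patefield",
) -> tuple[float, float]:
    """Monte-Carlo chi-squared independence test.

    Zero-margin rows/columns are dropped before testing.  ``null`` selects
    the null sampler: ``"patefield"`` draws tables uniformly conditional on
    both margins (the conditional test); ``"multinomial"`` resamples the
    whole table from the independence cell probabilities.
    """
    if B < 1:
        raise UsageError("B must be >= 1")
    obs = np.asarray(observed, dtype=np.int64)
    if obs.ndim != 2:
        raise UsageError("observed must be a 2-D table")
    rows = obs.sum(axis=1) > 0
    cols = obs.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        logger.warning("dropping %d empty rows / %d empty columns before testing",
                       int((~rows).sum()), int((~cols).sum()))
    obs = obs[np.ix_(rows, cols)]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError(
            f"table reduced to shape {obs.shape}; need >= 2x2 with positive margins"
        )
    exp = expected_table(obs)
    stat = _chisq_stat(obs.astype(float), exp)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if null == "patefield":
        sims = sps.random_table(obs.sum(axis=1), obs.sum(axis=0)).rvs(
            B, random_state=rng
        ).reshape(B, *obs.shape)
        sim_stats = ((sims - exp) ** 2 / exp).sum(axis=(1, 2))
    elif null == "multinomial":
        total = int(obs.sum())
        probs = (exp / total).ravel()
        sims = rng.multinomial(total, probs, size=B).reshape(B, *obs.shape).astype(float)
        sim_stats = np.empty(B)
        for b in range(B):
            t = sims[b]
            r, c = t.sum(axis=1), t.sum(axis=0)
            e = np.outer(r, c) / total
            sim_stats[b] = _chisq_stat(t, e)
    else:
        raise UsageError(f"unknown null sampler {null!r}")
    p = (1.0 + float((sim_stats >= stat - 1e-9).sum())) / (B + 1.0)
    return stat, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise UsageError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CouplingResults:
    """Gene-, pair- and dominance-level outputs of the coupling test."""

    genes: pd.DataFrame
    pairs: pd.DataFrame
    dominance: pd.DataFrame
    params: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(directory / "genes.tsv", sep="\t", index=False)
        self.pairs.to_csv(directory / "pairs.tsv", sep="\t", index=False)
        self.dominance.to_csv(directory / "dominance.tsv", sep="\t", index=False)
        (directory / "params.json").write_text(json.dumps(self.params, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CouplingResults":
        directory = Path(directory)
        return cls(
            genes=pd.read_csv(directory / "genes.tsv", sep="\t"),
            pairs=pd.read_csv(directory / "pairs.tsv", sep="\t"),
            dominance=pd.read_csv(directory / "dominance.tsv", sep="\t"),
            params=json.loads((directory / "params.json").read_text()),
        )


def _testable(matrix: np.ndarray, min_reads: int) -> bool:
    if matrix.sum() < min_reads:
        return False
    return (matrix.sum(axis=1) > 0).sum() >= 2 and (matrix.sum(axis=0) > 0).sum() >= 2


def estimate_promoter_dominance(
    counts: LinkCounts,
    db: IsoformDatabase,
    method: str = "chisq",
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    residual_cutoff: float = DEFAULT_RESIDUAL_CUTOFF,
    min_reads: int = DEFAULT_MIN_READS,
    dominance_threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    seed: int | None = None,
) -> CouplingResults:
    """Test every eligible gene for TSS-TES dependence and call dominance.

    Genes need >= 2 TSS clusters, >= 2 TES clusters and >= ``min_reads``
    full-length reads (with at least two non-empty rows and columns) to be
    tested; the rest are reported with ``tested = False``.
    """
    if method != "chisq":
        raise UsageError(f"unknown method {method!r}")
    for gid in counts.matrices:
        if gid not in db.genes:
            raise ConsistencyError(f"counts refer to gene {gid} absent from database")
        if (counts.tss_ids[gid] != [c.cluster_id for c in db.genes[gid].tss]
                or counts.tes_ids[gid] != [c.cluster_id for c in db.genes[gid].tes]):
            raise ConsistencyError(f"cluster ids of gene {gid} do not match database")

    gene_ids = sorted(counts.matrices)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(gene_ids))

    gene_rows, pair_rows, dom_rows = [], [], []
    tested_idx: list[int] = []
    for k, gid in enumerate(gene_ids):
        m = counts.matrices[gid]
        n = int(m.sum())
        multi = m.shape[0] >= 2 and m.shape[1] >= 2
        do_test = multi and _testable(m, min_reads)
        stat = p = np.nan
        if do_test:
            stat, p = chisq_mc_test(m, B=B, seed=np.random.default_rng(children[k]))
            tested_idx.append(len(gene_rows))
        gene_rows.append(
            dict(
                gene_id=gid, n_full_length=n,
                n_tss=m.shape[0], n_tes=m.shape[1],
                chisq_stat=stat, p_value=p, q_value=np.nan, tested=do_test,
            )
        )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "n_full_length", "n_tss", "n_tes",
                 "chisq_stat", "p_value", "q_value", "tested"],
    )
    if tested_idx:
        genes.loc[tested_idx, "q_value"] = bh_adjust(
            genes.loc[tested_idx, "p_value"].to_numpy()
        )

    qmap = dict(zip(genes.gene_id, genes.q_value))
    for gid in gene_ids:
        row = genes[genes.gene_id == gid].iloc[0]
        if not row.tested:
            continue
        m = counts.matrices[gid].astype(float)
        exp = expected_table(m)
        res = pearson_residuals(m)
        significant = bool(qmap[gid] <= alpha)
        for i, tss in enumerate(counts.tss_ids[gid]):
            for j, tes in enumerate(counts.tes_ids[gid]):
                pair_rows.append(
                    dict(
                        gene_id=gid, tss_id=tss, tes_id=tes,
                        observed_count=int(m[i, j]),
                        expected_count=exp[i, j],
                        residual=res[i, j],
                        coupled=bool(
                            significant and abs(res[i, j]) >= residual_cutoff
                        ),
                    )
                )
        colsums = m.sum(axis=0)
        for j, tes in enumerate(counts.tes_ids[gid]):
            if colsums[j] == 0:
                continue
            fracs = m[:, j] / colsums[j]
            imax = int(np.argmax(fracs))
            dominant = (
                counts.tss_ids[gid][imax]
                if significant and fracs[imax] >= dominance_threshold
                else ""
            )
            for i, tss in enumerate(counts.tss_ids[gid]):
                dom_rows.append(
                    dict(
                        gene_id=gid, tes_id=tes, tss_id=tss,
                        fraction=fracs[i], dominant_tss=dominant,
                    )
                )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["gene_id", "tss_id", "tes_id", "observed_count",
                 "expected_count", "residual", "coupled"],
    )
    dominance = pd.DataFrame(
        dom_rows, columns=["gene_id", "tes_id", "tss_id", "fraction", "dominant_tss"]
    )
    params = dict(
        method=method, B=B, alpha=alpha, residual_cutoff=residual_cutoff,
        min_reads=min_reads, dominance_threshold=dominance_threshold, seed=seed,
    )
    return CouplingResults(genes=genes, pairs=pairs, dominance=dominance, params=params)
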