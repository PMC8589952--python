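"""One-vs-rest marker discovery with the rank-sum test and the two filter cascades.

``find_all_markers`` tests every gene in every group against all remaining
cells with the tie-corrected Wilcoxon rank-sum normal approximation (see
:mod:`myotrace.stats`), computes average log2 fold-changes on un-logged
normalized means with pseudocount 1, and the fraction of expressing cells
inside/outside the group. Two downstream cascades mirror the study design:

* stage markers: adjusted p < 1e-10 and avg_log2FC > 0.5 (strict);
* deconvolution reference markers: avg_log2FC > 1 and pct_in > 0.5 in at
  least one group, minus mitochondrial/ribosomal genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, special, stats as sps

from .preprocess import mito_mask, ribo_mask

log = logging.getLogger(__name__)

LOW_N = 3  # groups smaller than this are flagged


@dataclass
class GeneList:
    """A named gene set (e.g. surface proteins, transcription factors)."""

    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = {g.strip() for g in self.genes if g and g.strip()}
        if not self.genes:
            raise ValueError(f"gene list {self.name!r} is empty")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneList":
        with open(path) as fh:
            genes = {line.strip() for line in fh if line.strip()}
        return cls(name=name or str(path), genes=genes)


def _dense(mat) -> np.ndarray:
    return mat.toarray() if sparse.issparse(mat) else np.asarray(mat, dtype=float)


def _tie_terms(x: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per gene (column)."""
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        _, counts = np.unique(x[:, j], return_counts=True)
        out[j] = float((counts**3 - counts).sum())
    return out


def rank_sum_groups(x: np.ndarray, masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-vs-rest rank-sum over genes for several group masks.

    ``x`` is cells x genes, ``masks`` is groups x cells boolean. Returns
    (U, p) arrays of shape groups x genes, matching
    :func:`myotrace.stats.rank_sum_test` gene by gene.
    """
    n = x.shape[0]
    ranks = sps.rankdata(x, axis=0)
    tie = _tie_terms(x)
    n1 = masks.sum(axis=1).astype(float)
    n2 = n - n1
    r1 = masks.astype(float) @ ranks
    u = r1 - (n1 * (n1 + 1) / 2.0)[:, None]
    mu = (n1 * n2 / 2.0)[:, None]
    var = (n1 * n2 / 12.0)[:, None] * ((n + 1) - tie[None, :] / (n * (n - 1)))
    z = np.zeros_like(u)
    ok = var > 0
    z[ok] = np.maximum(np.abs(u - mu)[ok] - 0.5, 0.0) / np.sqrt(var[ok])
    p = np.where(ok, 2.0 * special.ndtr(-z), 1.0)
    return u, np.minimum(p, 1.0)


def fold_change_stats(
    norm_matrix, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(avg_log2FC, pct_in, pct_out) per gene for one group mask.

    avg_log2FC = log2((mean_in(expm1) + 1) / (mean_out(expm1) + 1)) on the
    log-normalized matrix; pct is the fraction of cells with nonzero counts.
    """
    x = _dense(norm_matrix)
    mask = np.asarray(mask, dtype=bool)
    un = np.expm1(x)
    m_in = un[mask].mean(axis=0) if mask.any() else np.zeros(x.shape[1])
    m_out = un[~mask].mean(axis=0) if (~mask).any() else np.zeros(x.shape[1])
    lfc = np.log2((m_in + 1.0) / (m_out + 1.0))
    pct_in = (x[mask] > 0).mean(axis=0) if mask.any() else np.zeros(x.shape[1])
    pct_out = (x[~mask] > 0).mean(axis=0) if (~mask).any() else np.zeros(x.shape[1])
    return lfc, pct_in, pct_out


def find_all_markers(
    norm_matrix,
    groups: np.ndarray,
    gene_ids: np.ndarray,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-rest records for every gene x group.

    Adjustment is Bonferroni over the genes tested per group by default
    (``adjust="bh"`` switches to Benjamini-Hochberg). Groups with fewer than
    three cells are flagged ``low_n``.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    x = _dense(norm_matrix)
    gene_ids = np.asarray(gene_ids)
    n_genes = x.shape[1]
    masks = np.vstack([groups == g for g in levels])
    u, p = rank_sum_groups(x, masks)
    if adjust == "bonferroni":
        p_adj = np.minimum(p * n_genes, 1.0)
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p_adj = np.vstack([multipletests(row, method="fdr_bh")[1] for row in p])
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    # vectorized fold-change/pct over all groups (same formulas as
    # fold_change_stats, computed via mask matrix products)
    un = np.expm1(x)
    expressed = (x > 0).astype(float)
    m = masks.astype(float)
    n1 = m.sum(axis=1)
    col_sum_un = un.sum(axis=0)
    col_sum_ex = expressed.sum(axis=0)
    in_sum_un = m @ un
    in_sum_ex = m @ expressed
    with np.errstate(invalid="ignore", divide="ignore"):
        m_in = in_sum_un / n1[:, None]
        m_out = (col_sum_un[None, :] - in_sum_un) / (x.shape[0] - n1)[:, None]
        lfc_all = np.log2((m_in + 1.0) / (m_out + 1.0))
        pct_in_all = in_sum_ex / n1[:, None]
        pct_out_all = (col_sum_ex[None, :] - in_sum_ex) / (x.shape[0] - n1)[:, None]

    frames = []
    for i, g in enumerate(levels):
        lfc, pct_in, pct_out = lfc_all[i], pct_in_all[i], pct_out_all[i]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "group": g,
                    "U_statistic": u[i],
                    "p_value": p[i],
                    "p_adjusted": p_adj[i],
                    "avg_log2FC": lfc,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "low_n": masks[i].sum() < LOW_N,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def filter_stage_markers(
    records: pd.DataFrame, max_p_adjusted: float = 1e-10, min_log2fc: float = 0.5
) -> pd.DataFrame:
    """Stage cascade: keep p_adjusted < 1e-10 AND avg_log2FC > 0.5 (strict)."""
    keep = (records["p_adjusted"] < max_p_adjusted) & (records["avg_log2FC"] > min_log2fc)
    return records.loc[keep].reset_index(drop=True)


def filter_reference_markers(
    records: pd.DataFrame,
    gene_meta: pd.DataFrame,
    min_log2fc: float = 1.0,
    min_pct: float = 0.5,
) -> list[str]:
    """Reference cascade: avg_log2FC > 1 AND pct_in > 0.5 in >= 1 group,
    then drop mitochondrial and ribosomal genes. Returns the union gene set
    (sorted for determinism)."""
    keep = (records["avg_log2FC"] > min_log2fc) & (records["pct_in"] > min_pct)
    genes = set(records.loc[keep, "gene_id"])
    drop = set(gene_meta.loc[mito_mask(gene_meta) | ribo_mask(gene_meta), "gene_id"])
    return sorted(genes - drop)


def cross_reference(genes, gene_list: GeneList) -> set[str]:
    """Intersect a gene set with a curated list (whitespace-trimmed,
    case-sensitive symbols)."""
    gset = {str(g).strip() for g in genes}
    hits = gset & gene_list.genes
    if not hits:
        log.warning("no overlap between %d genes and list %r", len(gset), gene_list.name)
    return hits
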