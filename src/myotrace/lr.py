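"""Simplified ensemble ligand-receptor interaction scores between cell types.

The strength of a (ligand, receptor) pair from a sender type to a receiver
type is the product of the sender's mean log-normalized ligand expression and
the receiver's mean log-normalized receptor expression; multi-subunit
receptors contribute the minimum subunit mean (all subunits must be present
for signaling). This transparent product score deliberately does not
reproduce the Hill-function/trimean model of dedicated interaction-inference
tools. Significance comes from a label-permutation test with the add-one
p-value estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)

CATEGORIES = ("Secreted Signaling", "ECM-Receptor", "Cell-Cell Contact")


@dataclass
class LRDatabase:
    """(ligand, receptor, pathway, category) rows; receptor subunits are
    comma-separated in the receptor field."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"ligand", "receptor", "pathway", "category"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"LR database missing columns: {sorted(missing)}")
        if self.table.empty:
            raise ValueError("LR database is empty")
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown interaction categories: {sorted(bad)}")
        if self.table.duplicated(["ligand", "receptor"]).any():
            raise ValueError("duplicate (ligand, receptor) rows")

    @classmethod
    def from_tsv(cls, path) -> "LRDatabase":
        return cls(pd.read_csv(path, sep="\t"))


def _dense(mat) -> np.ndarray:
    return mat.toarray() if sparse.issparse(mat) else np.asarray(mat, dtype=float)


def _gene_means(x: np.ndarray, mask: np.ndarray, gene_pos: dict[str, int], genes: list[str]):
    """Mean expression of each named gene within the masked cells; None if absent."""
    out = []
    for g in genes:
        j = gene_pos.get(g)
        out.append(None if j is None else float(x[mask, j].mean()))
    return out


def pair_strength(
    norm_matrix,
    labels: np.ndarray,
    gene_ids: np.ndarray,
    sender: str,
    receiver: str,
    ligand: str,
    receptor: str,
) -> float:
    """mean(ligand | sender) x min over subunits of mean(subunit | receiver).

    A gene missing from the matrix scores 0 with a warning.
    """
    x = _dense(norm_matrix)
    labels = np.asarray(labels)
    gene_pos = {g: i for i, g in enumerate(np.asarray(gene_ids))}
    s_mask = labels == sender
    r_mask = labels == receiver
    if not s_mask.any() or not r_mask.any():
        raise ValueError("sender and receiver types must each have at least one cell")
    (lig_mean,) = _gene_means(x, s_mask, gene_pos, [ligand])
    subunits = [s.strip() for s in str(receptor).split(",")]
    sub_means = _gene_means(x, r_mask, gene_pos, subunits)
    if lig_mean is None or any(m is None for m in sub_means):
        log.warning("missing gene in pair (%s, %s); strength 0", ligand, receptor)
        return 0.0
    return float(lig_mean * min(sub_means))


def ensemble_strengths(
    norm_matrix,
    labels: np.ndarray,
    gene_ids: np.ndarray,
    db: LRDatabase,
    senders: list[str],
    receivers: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-pair scores, the sender x receiver aggregate matrix (sum over all
    pairs), and category subtotals per sender/receiver."""
    norm_matrix = _dense(norm_matrix)
    records = []
    for sender in senders:
        for receiver in receivers:
            for row in db.table.itertuples(index=False):
                s = pair_strength(
                    norm_matrix, labels, gene_ids, sender, receiver, row.ligand, row.receptor
                )
                records.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "ligand": row.ligand,
                        "receptor": row.receptor,
                        "pathway": row.pathway,
                        "category": row.category,
                        "strength": s,
                    }
                )
    scores = pd.DataFrame(records)
    aggregate = (
        scores.pivot_table(
            index="sender", columns="receiver", values="strength", aggfunc="sum"
        )
        .reindex(index=senders, columns=receivers)
        .fillna(0.0)
    )
    by_category = (
        scores.groupby(["sender", "receiver", "category"])["strength"].sum().reset_index()
    )
    return scores, aggregate, by_category


def permutation_test(
    norm_matrix,
    labels: np.ndarray,
    gene_ids: np.ndarray,
    sender: str,
    receiver: str,
    ligand: str,
    receptor: str,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Label-permutation p for one pair: p = (1 + #{perm >= obs}) / (n_perm + 1)."""
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    norm_matrix = _dense(norm_matrix)
    labels = np.asarray(labels)
    obs = pair_strength(norm_matrix, labels, gene_ids, sender, receiver, ligand, receptor)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        s = pair_strength(norm_matrix, perm, gene_ids, sender, receiver, ligand, receptor)
        if s >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
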