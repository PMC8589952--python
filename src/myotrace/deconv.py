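"""Cell-type reference profiles and per-spot transcript-fraction deconvolution.

Each spatial spot is treated as a small bulk RNA-seq mixture: its counts over
the reference marker genes are modeled as Multinomial(N, sum_k theta_k phi_k),
where phi_k is type k's transcript-probability profile (row-normalized mean
raw counts) and theta is the fraction of the spot's transcripts contributed by
each type. The maximum-likelihood theta is found by EM — a deterministic
point-estimate replacement for Gibbs-sampling deconvolution machinery, with
the same multinomial-mixture likelihood. The log-likelihood is concave in
theta for fixed phi, so the uniform start suffices and the EM iterates are
monotone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)

#: smoothing added to each profile entry, as a fraction of the row total
PROFILE_EPS = 1e-8


@dataclass
class ReferenceProfile:
    """Type x gene mean raw counts and the row-normalized form phi."""

    mean_counts: pd.DataFrame  # types x genes
    phi: np.ndarray
    type_names: list[str]
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        rs = self.phi.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1")


def build_profile_from_means(mean_counts: pd.DataFrame) -> ReferenceProfile:
    """Normalize a types x genes mean-count table into transcript probabilities."""
    means = mean_counts.to_numpy(dtype=float)
    if (means < 0).any():
        raise ValueError("mean counts must be nonnegative")
    totals = means.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        bad = [str(mean_counts.index[i]) for i in zero]
        raise ValueError(f"type(s) with all-zero profile: {bad}")
    smoothed = means + (PROFILE_EPS * totals)[:, None]
    phi = smoothed / smoothed.sum(axis=1, keepdims=True)
    return ReferenceProfile(
        mean_counts=mean_counts,
        phi=phi,
        type_names=[str(t) for t in mean_counts.index],
        gene_ids=mean_counts.columns.to_numpy(),
    )


def build_profiles(
    counts: sparse.spmatrix,
    type_labels: np.ndarray,
    gene_ids: np.ndarray,
    marker_genes: set[str] | list[str],
) -> ReferenceProfile:
    """Mean raw counts per type over the reference marker genes.

    Marker genes are kept in the order they appear in ``gene_ids``; a type
    with zero cells is an error (it cannot contribute a profile).
    """
    gene_ids = np.asarray(gene_ids)
    marker_set = set(marker_genes)
    unknown = marker_set - set(gene_ids)
    if unknown:
        raise ValueError(f"marker genes absent from the gene universe: {sorted(unknown)[:5]}")
    col_mask = np.isin(gene_ids, list(marker_set))
    sub = sparse.csr_matrix(counts)[:, col_mask]
    labels = pd.Series(np.asarray(type_labels))
    rows = {}
    for t, idx in labels.groupby(labels).groups.items():
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty groups
            raise ValueError(f"type {t!r} has zero cells")
        rows[t] = np.asarray(sub[np.asarray(idx)].mean(axis=0)).ravel()
    mean_counts = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids[col_mask])
    mean_counts = mean_counts.sort_index()
    return build_profile_from_means(mean_counts)


@dataclass
class ThetaResult:
    theta: np.ndarray
    log_likelihood: float
    ll_trace: np.ndarray
    n_iter: int
    converged: bool
    degenerate: bool = False  # zero usable counts -> uniform theta


def estimate_theta(
    spot_counts: np.ndarray,
    profiles: ReferenceProfile,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> ThetaResult:
    """Maximum-likelihood transcript fractions for one spot by EM.

    Update: theta_k <- (1/N) * sum_g x_g * theta_k phi_kg / (sum_j theta_j phi_jg),
    from a uniform start; stops when the relative log-likelihood change drops
    below ``tol``. The update preserves the simplex constraint analytically
    and never decreases the log-likelihood.
    """
    x = np.asarray(spot_counts, dtype=float).ravel()
    phi = profiles.phi
    k = phi.shape[0]
    n = x.sum()
    if n <= 0:
        warnings.warn("spot has zero usable counts; returning uniform theta")
        return ThetaResult(np.full(k, 1.0 / k), np.nan, np.array([]), 0, False, degenerate=True)
    nz = x > 0
    xz = x[nz]
    phz = phi[:, nz]
    theta = np.full(k, 1.0 / k)
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = theta @ phz
        ll = float(xz @ np.log(mix))
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        theta = theta * (phz @ (xz / mix)) / n
        theta /= theta.sum()  # guard float drift; analytically already 1
    return ThetaResult(theta, trace[-1], np.asarray(trace), it, converged)


@dataclass
class SpotComposition:
    """Per-spot transcript fractions plus fit diagnostics."""

    theta: pd.DataFrame  # spots x types
    log_likelihood: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray
    outside_fraction: np.ndarray  # fraction of spot counts on genes not in the profile

    def validate(self) -> None:
        th = self.theta.to_numpy()
        if (th < -1e-12).any() or not np.allclose(th.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("theta rows must be nonnegative and sum to 1")


def deconvolve(
    spots,
    profiles: ReferenceProfile,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> SpotComposition:
    """Estimate theta for every spot over the spot/profile gene intersection."""
    gene_ids = np.asarray(spots.gene_ids)
    prof_genes = np.asarray(profiles.gene_ids)
    common = np.isin(gene_ids, prof_genes)
    if not common.any():
        raise ValueError("no overlap between spot genes and profile genes")
    # identical profiles make theta non-identifiable; EM then just keeps the start
    if len(profiles.type_names) > 1:
        ph = profiles.phi
        for a in range(ph.shape[0]):
            for b in range(a + 1, ph.shape[0]):
                if np.allclose(ph[a], ph[b], atol=1e-12):
                    log.warning(
                        "profiles %s and %s are identical; theta between them is non-identifiable",
                        profiles.type_names[a],
                        profiles.type_names[b],
                    )
    counts = sparse.csr_matrix(spots.counts)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    sub = counts[:, common].toarray()
    # align columns to profile gene order
    order = pd.Index(prof_genes).get_indexer(gene_ids[common])
    aligned = np.zeros((sub.shape[0], len(prof_genes)))
    aligned[:, order] = sub
    inside = aligned.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        outside = np.where(totals > 0, 1.0 - inside / totals, 0.0)

    thetas, lls, iters, conv = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(aligned.shape[0]):
            res = estimate_theta(aligned[i], profiles, max_iter=max_iter, tol=tol)
            thetas.append(res.theta)
            lls.append(res.log_likelihood)
            iters.append(res.n_iter)
            conv.append(res.converged)
    theta = pd.DataFrame(np.vstack(thetas), columns=profiles.type_names)
    if "spot_id" in spots.spot_meta.columns:
        theta.index = spots.spot_meta["spot_id"].to_numpy()
    comp = SpotComposition(
        theta=theta,
        log_likelihood=np.asarray(lls),
        n_iter=np.asarray(iters),
        converged=np.asarray(conv),
        outside_fraction=outside,
    )
    comp.validate()
    return comp
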