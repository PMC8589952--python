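"""Within-spot cell-type co-occurrence tallies from deconvolved theta values.

For each spot, the types present are the up-to-10 highest-theta types with
theta >= 0.01 (a type at exactly 0.01 counts; ties at the cutoff rank are
broken by type name). Every unordered pair of present types increments the
pairwise tally and every present type its diagonal; matrices are accumulated
per timepoint stratum and overall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

OVERALL = "overall"


def present_types(
    theta: pd.Series | np.ndarray,
    type_names=None,
    max_n: int = 10,
    min_theta: float = 0.01,
) -> list[str]:
    """Types with theta >= min_theta, by descending theta, truncated to max_n."""
    if isinstance(theta, pd.Series):
        names = theta.index.to_numpy()
        vals = theta.to_numpy(dtype=float)
    else:
        vals = np.asarray(theta, dtype=float)
        names = np.asarray(type_names if type_names is not None else np.arange(len(vals)))
    order = sorted(range(len(vals)), key=lambda i: (-vals[i], str(names[i])))
    kept = [str(names[i]) for i in order if vals[i] >= min_theta]
    if len(kept) > max_n:
        log.debug("truncating %d present types to top %d", len(kept), max_n)
    return kept[:max_n]


@dataclass
class CooccurrenceResult:
    """Symmetric type x type tallies per stratum (plus ``overall``)."""

    tallies: dict[str, pd.DataFrame]
    spot_counts: dict[str, int]

    def frequencies(self, stratum: str = OVERALL) -> pd.DataFrame:
        """Tallies as a fraction of the stratum's spots."""
        n = self.spot_counts[stratum]
        return self.tallies[stratum] / n if n else self.tallies[stratum] * np.nan


def tally(
    theta: pd.DataFrame,
    strata,
    max_n: int = 10,
    min_theta: float = 0.01,
) -> CooccurrenceResult:
    """Accumulate co-occurrence matrices over spots, stratified and overall."""
    strata = np.asarray(strata)
    if len(strata) != len(theta):
        raise ValueError("one stratum label per spot required")
    types = [str(c) for c in theta.columns]
    idx = {t: i for i, t in enumerate(types)}
    k = len(types)
    levels = [str(s) for s in pd.unique(strata)]
    mats = {s: np.zeros((k, k), dtype=int) for s in [*levels, OVERALL]}
    counts = {s: 0 for s in [*levels, OVERALL]}
    vals = theta.to_numpy(dtype=float)
    for row, stratum in zip(vals, strata):
        s = str(stratum)
        pres = [idx[t] for t in present_types(row, type_names=types, max_n=max_n, min_theta=min_theta)]
        for target in (mats[s], mats[OVERALL]):
            for a_i, a in enumerate(pres):
                target[a, a] += 1
                for b in pres[a_i + 1 :]:
                    target[a, b] += 1
                    target[b, a] += 1
        counts[s] += 1
        counts[OVERALL] += 1
    tallies = {s: pd.DataFrame(m, index=types, columns=types) for s, m in mats.items()}
    return CooccurrenceResult(tallies=tallies, spot_counts=counts)
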