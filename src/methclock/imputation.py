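"""Imputation of clock probes missing from a beta matrix.

Clocks require every one of their probes; arrays and filtered matrices do
not always supply them.  Three resolutions are offered:

* ``reference_mean`` — fill a probe from a gold-standard cohort's mean
  beta (the behaviour of the widely used online Horvath calculator).
* ``cohort_mean`` — fill missing cells of a probe with the probe's own
  observed mean in the cohort; cannot resolve a probe observed nowhere.
* ``knn`` — fill missing cells from the k nearest complete probe rows by
  Euclidean distance (the `impute`-style workflow used with the Hannum
  clock); cannot resolve a probe observed nowhere.
* ``constant`` — fill with a fixed beta value.

All operations return a new matrix; inputs are never modified, and
imputing an already-complete matrix is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .clock_core import BetaMatrix

logger = logging.getLogger(__name__)

DEFAULT_KNN_K = 10


@dataclass(frozen=True)
class ImputationPolicy:
    """How to resolve missing clock probes before scoring.

    ``reference_means`` may be supplied alongside ``cohort_mean`` or
    ``knn`` as a fallback for probes with no observed value at all.
    """

    method: str  # reference_mean | cohort_mean | knn | constant
    k: int = DEFAULT_KNN_K
    constant_value: float | None = None
    reference_means: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.method not in ("reference_mean", "cohort_mean", "knn", "constant"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.method == "reference_mean" and self.reference_means is None:
            raise ValueError("reference_mean imputation needs reference_means")
        if self.method == "knn" and self.k < 1:
            raise ValueError("knn imputation needs k >= 1")
        if self.method == "constant":
            if self.constant_value is None:
                raise ValueError("constant imputation needs constant_value")
            if not 0.0 <= self.constant_value <= 1.0:
                raise ValueError("constant_value must lie in [0, 1]")
        if self.reference_means is not None:
            object.__setattr__(self, "reference_means", dict(self.reference_means))

    def can_resolve_absent_probes(self) -> bool:
        """Whether probes with zero observed values can be filled."""
        return self.method in ("reference_mean", "constant") or (
            self.reference_means is not None
        )


# ---------------------------------------------------------------------------
# Frame-level workers (operate on probes x samples DataFrames with NaN holes)
# ---------------------------------------------------------------------------

def _reference_mean_fill(frame: pd.DataFrame,
                         reference_means: Mapping[str, float]) -> pd.DataFrame:
    missing_rows = frame.isna().any(axis=1)
    needed = frame.index[missing_rows]
    uncovered = [p for p in needed if p not in reference_means]
    if uncovered:
        raise ValueError(
            f"reference means missing for {len(uncovered)} probes: {uncovered[:10]}"
        )
    out = frame.copy()
    for p in needed:
        mu = float(reference_means[p])
        if not 0.0 <= mu <= 1.0:
            raise ValueError(f"reference mean for {p} outside [0, 1]: {mu}")
        out.loc[p] = out.loc[p].fillna(mu)
    return out


def _cohort_mean_fill(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    row_means = frame.mean(axis=1)  # skips NaN
    out = frame.where(frame.notna(), row_means, axis=0)
    unresolved = out.index[out.isna().any(axis=1)].tolist()
    return out, unresolved


def _knn_fill(frame: pd.DataFrame, k: int) -> tuple[pd.DataFrame, list[str]]:
    """kNN over probe rows; neighbours drawn from fully observed rows.

    Distances are plain Euclidean sums over the columns where the target
    row is observed; ties are broken by probe-ID lexicographic order.
    Rows with no eligible neighbour fall back to the cohort (row) mean.
    """
    values = frame.to_numpy()
    obs = ~np.isnan(values)
    complete = obs.all(axis=1)
    targets = np.flatnonzero(~complete)
    out = values.copy()
    probe_ids = frame.index.to_numpy()

    candidates = np.flatnonzero(complete)
    if len(candidates) and len(targets):
        if k > len(candidates):
            logger.warning(
                "knn imputation: k=%d exceeds the %d complete probes; using all",
                k, len(candidates),
            )
        k_eff = min(k, len(candidates))
        cand_vals = values[candidates]
        # lexicographic tie-break on probe ID within equal distances
        cand_order_key = np.argsort(probe_ids[candidates], kind="stable")
        for t in targets:
            mask = obs[t]
            if not mask.any():
                continue  # nothing observed: no distance defined, fall through
            diffs = cand_vals[:, mask] - values[t, mask]
            dist = np.sqrt((diffs * diffs).sum(axis=1))
            # sort by (distance, probe id): apply id order first, stable-sort on distance
            by_id = cand_order_key
            order = by_id[np.argsort(dist[by_id], kind="stable")]
            chosen = candidates[order[:k_eff]]
            fill_cols = np.flatnonzero(~mask)
            out[t, fill_cols] = values[np.ix_(chosen, fill_cols)].mean(axis=0)

    filled = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    still = filled.isna().any(axis=1)
    if still.any():
        filled, unresolved = _cohort_mean_fill(filled)
    else:
        unresolved = []
    return filled, unresolved


# ---------------------------------------------------------------------------
# Public operations on BetaMatrix
# ---------------------------------------------------------------------------

def _with_needed(betas: BetaMatrix, needed_probes: Iterable[str] | None) -> pd.DataFrame:
    """Beta frame extended with all-NaN rows for needed-but-absent probes."""
    frame = betas.data
    if needed_probes is None:
        return frame.copy()
    needed = pd.Index(list(needed_probes)).astype(str)
    extra = needed.difference(frame.index)
    full_index = frame.index.append(extra)
    return frame.reindex(full_index)


def impute_reference_mean(
    betas: BetaMatrix,
    reference_means: Mapping[str, float],
    needed_probes: Iterable[str] | None = None,
) -> BetaMatrix:
    """Fill absent probes and missing cells from gold-standard means.

    Every probe in ``needed_probes`` absent from ``betas`` is added as a
    constant row; missing cells of present probes are filled the same
    way.  A needed probe without a reference mean is a hard error.
    """
    frame = _with_needed(betas, needed_probes)
    return BetaMatrix(_reference_mean_fill(frame, reference_means), validate=False)


def impute_cohort_mean(
    betas: BetaMatrix, needed_probes: Iterable[str] | None = None
) -> BetaMatrix:
    """Fill each probe's missing cells with the probe's observed mean.

    Probes with no observed value remain NaN (reported via log warning);
    downstream scoring escalates them to a hard error.
    """
    frame = _with_needed(betas, needed_probes)
    out, unresolved = _cohort_mean_fill(frame)
    if unresolved:
        logger.warning(
            "cohort-mean imputation left %d probes unresolved (no observed "
            "values): %s", len(unresolved), unresolved[:10],
        )
    return BetaMatrix(out, validate=False)


def impute_knn(betas: BetaMatrix, k: int = DEFAULT_KNN_K) -> BetaMatrix:
    """Fill missing cells from the k nearest complete probe rows.

    Deterministic: distance ties are broken by probe-ID order.  A row
    with no eligible neighbour falls back to its cohort mean; rows with
    no observed values at all stay NaN.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if betas.n_probes < 2:
        raise ValueError("knn imputation needs at least 2 probes")
    out, unresolved = _knn_fill(betas.data, k)
    if unresolved:
        logger.warning(
            "knn imputation left %d probes unresolved: %s",
            len(unresolved), unresolved[:10],
        )
    return BetaMatrix(out, validate=False)


def resolve_clock_probes(frame: pd.DataFrame, policy: ImputationPolicy) -> pd.DataFrame:
    """Apply a policy to a clock-probe frame (NaN rows for absent probes).

    Used by :func:`methclock.clock_core.apply_clock`; ``reference_means``
    on the policy acts as a final fallback for probes the primary method
    cannot resolve.
    """
    if policy.method == "reference_mean":
        return _reference_mean_fill(frame, policy.reference_means)
    if policy.method == "constant":
        return frame.fillna(policy.constant_value)
    if policy.method == "cohort_mean":
        out, unresolved = _cohort_mean_fill(frame)
    else:  # knn
        out, unresolved = _knn_fill(frame, policy.k)
    if unresolved and policy.reference_means is not None:
        out = _reference_mean_fill(out, policy.reference_means)
    return out
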