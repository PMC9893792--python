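"""Network-level resting-state connectivity summaries from ROI time series.

Per subject-visit: an ROI-by-ROI Pearson correlation matrix is Fisher
z-transformed, then a validity mask removes (a) the diagonal, (b) ROI pairs
whose centers lie within 20 mm of one another (short-distance correlations
are dominated by shared spatial smoothing), and (c) negative correlations
(their interpretation in resting-state data is ambiguous). Valid pairs are
averaged into:

* one within-network value per named network (pairs inside the network);
* one value per unordered network pair (45 pairs for 10 networks);
* a per-network between value — by default the pooled mean over all valid
  ROI pairs spanning that network and the other nine (``between_mode=
  "pooled"``), or alternatively the unweighted mean of its nine pair-block
  values (``between_mode="blocks"``);
* ``overall_within`` = unweighted mean of the 10 within values and
  ``overall_between`` = unweighted mean of the 45 pair values.

Unassigned ROIs never enter any summary. Excluded pairs are excluded from
both numerator and denominator — they are not averaged in as zeros. A block
with no valid pair yields NaN, which propagates to the overall means rather
than being silently replaced. Means are taken on the z scale by default;
``domain="r"`` averages raw correlations instead for sensitivity analyses.

Longitudinal change is follow-up minus baseline, field-wise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import NETWORKS, Parcellation

logger = logging.getLogger(__name__)

DISTANCE_THRESHOLD_MM = 20.0

NETWORK_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(NETWORKS, 2)
)


def pearson_matrix(ts) -> np.ndarray:
    """Full Pearson correlation matrix of an ROI time-series table (T x p).

    Requires at least 3 time points and no constant column; a zero-variance
    column is reported by ROI position (and id, for a DataFrame).
    """
    if isinstance(ts, pd.DataFrame):
        names = list(ts.columns)
        x = ts.to_numpy(dtype=float)
    else:
        x = np.asarray(ts, dtype=float)
        names = list(range(x.shape[1]))
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("time series must be 2-D with at least 3 time points")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance ROI column(s): {[names[i] for i in bad]}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return r


def fisher_z(r):
    """Fisher z-transform, z = arctanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class ConnectivityMatrix:
    """Fisher-z matrix plus validity mask and exclusion tallies."""

    z: np.ndarray
    valid: np.ndarray
    n_distance_excluded: int  # off-diagonal pairs under the distance threshold
    n_negative_excluded: int  # remaining pairs excluded for negative r
    r: np.ndarray = field(repr=False, default=None)

    @property
    def exclusion_stats(self) -> dict[str, int]:
        return {
            "n_distance_excluded": self.n_distance_excluded,
            "n_negative_excluded": self.n_negative_excluded,
        }


def apply_exclusions(
    r_matrix: np.ndarray,
    parcellation: Parcellation,
    distance_threshold: float = DISTANCE_THRESHOLD_MM,
) -> ConnectivityMatrix:
    """Mask the diagonal, short-distance pairs (< threshold), and negatives.

    Distances are strict: a pair at exactly the threshold separation stays
    valid. The z matrix keeps a value for every off-diagonal pair; the mask
    alone decides what enters a mean. Off-diagonal |r| = 1 (degenerate,
    e.g. duplicated series) is nudged inside (-1, 1) before the transform.
    """
    r = np.asarray(r_matrix, dtype=float)
    n = len(parcellation.table)
    if r.shape != (n, n):
        raise ValueError(f"matrix shape {r.shape} does not match {n} ROIs")
    offdiag = ~np.eye(n, dtype=bool)
    dist = parcellation.pairwise_distances()
    far_enough = dist >= distance_threshold
    nonneg = r >= 0
    valid = offdiag & far_enough & nonneg
    n_dist = int((offdiag & ~far_enough).sum() // 2)
    n_neg = int((offdiag & far_enough & ~nonneg).sum() // 2)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        z=z, valid=valid, n_distance_excluded=n_dist, n_negative_excluded=n_neg, r=r
    )


@dataclass
class NetworkSummary:
    """Within/between network connectivity means for one subject-visit."""

    visit: str
    within: dict[str, float]  # 10 values, one per network
    between_pairs: dict[tuple[str, str], float]  # 45 network-pair values
    between_by_network: dict[str, float]  # 10 values
    overall_within: float
    overall_between: float
    domain: str = "z"
    between_mode: str = "pooled"
    subject: object = None

    def to_series(self) -> pd.Series:
        data = {
            "overall_between": self.overall_between,
            "overall_within": self.overall_within,
        }
        for net in NETWORKS:
            data[f"within_{net}"] = self.within[net]
        for net in NETWORKS:
            data[f"between_{net}"] = self.between_by_network[net]
        return pd.Series(data)


def _masked_mean(values: np.ndarray, mask: np.ndarray) -> float:
    k = int(mask.sum())
    return float(values[mask].sum() / k) if k else float("nan")


def network_means(
    cm: ConnectivityMatrix,
    parcellation: Parcellation,
    visit: str = "",
    domain: str = "z",
    between_mode: str = "pooled",
    subject=None,
) -> NetworkSummary:
    """Aggregate a masked connectivity matrix into network-level means."""
    if domain not in ("z", "r"):
        raise ValueError("domain must be 'z' or 'r'")
    if between_mode not in ("pooled", "blocks"):
        raise ValueError("between_mode must be 'pooled' or 'blocks'")
    mat = cm.z if domain == "z" else cm.r
    if mat is None:
        raise ValueError("raw correlations unavailable for domain='r'")
    idx = {net: parcellation.network_indices(net) for net in NETWORKS}

    within: dict[str, float] = {}
    for net, ix in idx.items():
        sub = mat[np.ix_(ix, ix)]
        msk = cm.valid[np.ix_(ix, ix)]
        triu = np.triu(np.ones_like(msk, dtype=bool), k=1)
        within[net] = _masked_mean(sub, msk & triu)
        if np.isnan(within[net]):
            logger.warning("no valid within-network pairs for %s", net)

    between_pairs: dict[tuple[str, str], float] = {}
    for a, b in NETWORK_PAIRS:
        sub = mat[np.ix_(idx[a], idx[b])]
        msk = cm.valid[np.ix_(idx[a], idx[b])]
        between_pairs[(a, b)] = _masked_mean(sub, msk)
        if np.isnan(between_pairs[(a, b)]):
            logger.warning("no valid pairs between %s and %s", a, b)

    between_by_network: dict[str, float] = {}
    for net in NETWORKS:
        if between_mode == "pooled":
            others = np.concatenate([idx[o] for o in NETWORKS if o != net])
            sub = mat[np.ix_(idx[net], others)]
            msk = cm.valid[np.ix_(idx[net], others)]
            between_by_network[net] = _masked_mean(sub, msk)
        else:
            vals = [
                between_pairs[(a, b)] for a, b in NETWORK_PAIRS if net in (a, b)
            ]
            between_by_network[net] = float(np.mean(vals))

    overall_within = float(np.mean(list(within.values())))
    overall_between = float(np.mean(list(between_pairs.values())))
    return NetworkSummary(
        visit=visit,
        within=within,
        between_pairs=between_pairs,
        between_by_network=between_by_network,
        overall_within=overall_within,
        overall_between=overall_between,
        domain=domain,
        between_mode=between_mode,
        subject=subject,
    )


def summarize_timeseries(
    ts,
    parcellation: Parcellation,
    visit: str = "",
    distance_threshold: float = DISTANCE_THRESHOLD_MM,
    domain: str = "z",
    between_mode: str = "pooled",
    subject=None,
) -> NetworkSummary:
    """Convenience: correlation -> exclusions -> network means."""
    r = pearson_matrix(ts)
    cm = apply_exclusions(r, parcellation, distance_threshold)
    return network_means(
        cm, parcellation, visit=visit, domain=domain,
        between_mode=between_mode, subject=subject,
    )


def connectivity_delta(
    baseline: NetworkSummary, followup: NetworkSummary
) -> pd.Series:
    """Field-wise follow-up minus baseline summary values."""
    if baseline.subject != followup.subject:
        raise ValueError("visit summaries belong to different subjects")
    delta = followup.to_series() - baseline.to_series()
    delta.index = [f"delta_{c}" for c in delta.index]
    return delta


def delta_table(
    summaries: dict[object, dict[str, NetworkSummary]]
) -> pd.DataFrame:
    """Per-subject Δ summary table; subjects missing a visit are dropped."""
    rows = []
    for subject, visits in summaries.items():
        if "baseline" not in visits or "followup" not in visits:
            logger.warning("subject %s missing a visit; dropped from deltas", subject)
            continue
        row = connectivity_delta(visits["baseline"], visits["followup"])
        row["subject"] = subject
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df[["subject"] + [c for c in df.columns if c != "subject"]]
    return df.reset_index(drop=True)
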