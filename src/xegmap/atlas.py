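"""knn label transfer onto a reference atlas with confidence-based rejection.

Each query cell takes the modal cell type among its k Euclidean nearest
atlas neighbors (k = 50 by default), with confidence = modal count / k, the
mean neighbor distance, and the mean and standard deviation of the
neighbors' developmental ages. Cells are demoted to "Not assigned" when the
mean neighbor distance falls in the long tail of its distribution (99th
percentile by default, or an explicit threshold), when confidence < 0.5,
when the surviving assigned type holds fewer than 10 cells, or when the
type is on an exclusion list.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import AtlasReference, CorrectedSpace

NOT_ASSIGNED = "Not assigned"


@dataclass
class RejectionRule:
    """Distance-tail rule, a reproducible proxy for an eyeballed histogram cut.

    Default: reject cells whose mean neighbor distance exceeds
    median + n_mads * 1.4826 * MAD of the per-dataset distribution — robust
    to the tail itself, so it still works when the poorly-mapping population
    is larger than a fixed quantile would allow. Alternatives: a fixed
    ``quantile``, or an explicit ``threshold`` (which wins over both).
    """

    n_mads: float | None = 3.0
    quantile: float | None = None
    threshold: float | None = None

    def cutoff(self, mean_distances: np.ndarray) -> float:
        if self.threshold is not None:
            return float(self.threshold)
        if self.quantile is not None:
            return float(np.quantile(mean_distances, self.quantile))
        med = float(np.median(mean_distances))
        mad = float(np.median(np.abs(mean_distances - med)))
        return med + self.n_mads * 1.4826 * mad


def map_to_atlas(query: CorrectedSpace, atlas: AtlasReference, k: int = 50) -> pd.DataFrame:
    """Assign each query cell the modal type of its k atlas nearest neighbors.

    Ties on the modal count break by smaller mean distance to the tied
    type's neighbors, then lexicographically. Returns one row per query cell
    with assigned_type, confidence, mean_nn_distance, age_mean, age_sd, k.
    """
    if query.coordinates.shape[1] != atlas.coordinates.shape[1]:
        raise ValueError(
            f"dimension mismatch: query d={query.coordinates.shape[1]}, "
            f"atlas d={atlas.coordinates.shape[1]}"
        )
    if k > atlas.n_cells:
        raise ValueError(f"k={k} exceeds atlas size {atlas.n_cells}")
    nn = NearestNeighbors(n_neighbors=k).fit(atlas.coordinates)
    dist, idx = nn.kneighbors(query.coordinates)
    types = atlas.type_label[idx]  # n_query x k
    ages = atlas.timepoint[idx]

    assigned = np.empty(len(idx), dtype=object)
    confidence = np.empty(len(idx))
    for i in range(len(idx)):
        labels, counts = np.unique(types[i], return_counts=True)
        top = counts.max()
        tied = labels[counts == top]
        if len(tied) > 1:
            mean_d = [dist[i][types[i] == t].mean() for t in tied]
            ranked = sorted(zip(mean_d, tied))
            winner = ranked[0][1]
        else:
            winner = tied[0]
        assigned[i] = winner
        confidence[i] = top / k
    return pd.DataFrame(
        {
            "cell_id": query.cell_ids,
            "assigned_type": assigned,
            "confidence": confidence,
            "mean_nn_distance": dist.mean(axis=1),
            "age_mean": ages.mean(axis=1),
            "age_sd": ages.std(axis=1, ddof=0),
            "k": k,
        }
    )


def apply_rejection(
    assignments: pd.DataFrame,
    conf_min: float = 0.5,
    dist_rule: RejectionRule | None = None,
    min_cluster: int = 10,
    excluded_types: set | None = None,
) -> pd.DataFrame:
    """Demote unreliable assignments to "Not assigned".

    Rule order: distance tail, then confidence < conf_min (strict: exactly
    conf_min is retained), then types left with < min_cluster members, then
    explicitly excluded types.
    """
    dist_rule = dist_rule or RejectionRule()
    excluded_types = excluded_types or set()
    out = assignments.copy()
    cutoff = dist_rule.cutoff(out["mean_nn_distance"].to_numpy())
    reject = out["mean_nn_distance"].to_numpy() > cutoff
    reject |= out["confidence"].to_numpy() < conf_min
    surviving = out.loc[~reject, "assigned_type"]
    small = {t for t, n in surviving.value_counts().items() if n < min_cluster}
    reject |= out["assigned_type"].isin(small).to_numpy()
    reject |= out["assigned_type"].isin(excluded_types).to_numpy()
    out.loc[reject, "assigned_type"] = NOT_ASSIGNED
    return out


def type_frequencies(assignments: pd.DataFrame, group_col: str = "sample") -> pd.DataFrame:
    """Per-group, per-type counts and fractions (fractions sum to 1 per group)."""
    if group_col not in assignments.columns:
        raise ValueError(f"missing grouping column {group_col!r}")
    rows = []
    for group, sub in assignments.groupby(group_col, sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {group!r}")
        counts = sub["assigned_type"].value_counts()
        for t, n in counts.items():
            rows.append({group_col: group, "type": t, "count": int(n), "fraction": n / len(sub)})
    return pd.DataFrame(rows)
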