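"""Identify spiked-in control cells.

ES spike-ins carry the mCherry transgene and are flagged on any expression.
E14 and XEN spike-ins are hashed with Ab_CD15 / Ab_CD140 antibodies and are
called only when both the antibody count exceeds its strict threshold AND
the cell sits in the designated cluster; cluster membership alone marks
XEN-derived cells (eGFP-positive cluster, below the CD140 threshold). When
several rules fire, precedence is mCherry > CD15 > CD140.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .qc import signature_score

ES_MCHERRY = "ES (mCherry+)"
E14_CD15 = "E14 (CD15+)"
XEN_SPIKEIN = "XEN spike-in (CD140+)"
XEN_DERIVED = "XEN derived (CD140-)"
NONE = "none"


def flag_transgene(m: CountMatrix, gene: str) -> np.ndarray:
    """True where the transgene has any raw expression (count > 0)."""
    gi = m.gene_index([gene])[0]
    return np.asarray(m.values[gi, :].todense()).ravel() > 0


@dataclass
class SpikeinRule:
    antibody: str  # antibody feature name
    threshold: float  # strict: count must exceed it
    clusters: set = field(default_factory=set)  # designated cluster ids

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")


def designate_cluster(
    clusters: np.ndarray, nm, marker_genes, top: int = 1
) -> set:
    """Pick the cluster(s) with highest mean marker-signature score.

    A reproducible stand-in for choosing clusters by literature markers and
    spike-in gene expression by eye.
    """
    score = signature_score(nm, marker_genes)
    means = pd.Series(score).groupby(pd.Series(clusters)).mean()
    return set(means.sort_values(ascending=False).index[:top])


def identify_spikeins(
    clusters: np.ndarray,
    antibodies: pd.DataFrame,
    mcherry_pos: np.ndarray,
    cd15_rule: SpikeinRule,
    cd140_rule: SpikeinRule | None = None,
    xen_derived_clusters: set | None = None,
) -> np.ndarray:
    """Per-cell annotation over the spike-in classes.

    ``antibodies`` has one row per cell in matrix order. ``cd140_rule`` and
    ``xen_derived_clusters`` apply to the XEG experiment only (pass None for
    gastruloids, which carry no XEN populations).
    """
    n = len(clusters)
    if len(antibodies) != n or len(mcherry_pos) != n:
        raise ValueError("cluster labels and antibody counts must cover all cells")
    known = set(np.unique(clusters).tolist())
    for rule in (cd15_rule, cd140_rule):
        if rule is not None and not set(rule.clusters) <= known:
            raise ValueError(
                f"rule references unknown cluster(s) {set(rule.clusters) - known}"
            )
    out = np.full(n, NONE, dtype=object)
    if cd140_rule is not None:
        xen_clusters = set(cd140_rule.clusters) | set(xen_derived_clusters or set())
        in_xen = np.isin(clusters, list(xen_clusters))
        cd140 = antibodies[cd140_rule.antibody].to_numpy()
        in_cd140_cluster = np.isin(clusters, list(cd140_rule.clusters))
        out[in_cd140_cluster & (cd140 > cd140_rule.threshold)] = XEN_SPIKEIN
        out[in_xen & (out == NONE)] = XEN_DERIVED
    cd15 = antibodies[cd15_rule.antibody].to_numpy()
    in_cd15_cluster = np.isin(clusters, list(cd15_rule.clusters))
    out[in_cd15_cluster & (cd15 > cd15_rule.threshold)] = E14_CD15
    out[mcherry_pos] = ES_MCHERRY  # highest precedence
    return out
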