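"""Group-level comparison of individualized networks.

Edges of the per-subject networks (their Z weights, or the raw
correlation differences) are compared between two groups with an
unpaired two-sample t-test per edge, Bonferroni-corrected over all
R(R-1)/2 edges. A per-edge incidence map summarizes how heterogeneously
the individually significant edges are distributed across patients.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import IDSCN, upper_triangle

__all__ = ["group_edge_ttest", "edge_incidence", "stack_edge_vectors"]


def stack_edge_vectors(networks: Sequence[IDSCN], on: str = "z") -> np.ndarray:
    """Stack per-subject edge vectors (subjects x edges, canonical i<j
    order). ``on`` selects the Z weights ("z") or raw deltas ("delta")."""
    if not networks:
        raise ValueError("empty group")
    labels = networks[0].region_labels
    for net in networks:
        if net.region_labels != labels:
            raise ValueError(
                f"region labels of subject {net.subject_id!r} differ from the group"
            )
    iu = upper_triangle(len(labels))
    attr = {"z": "z_matrix", "delta": "delta_matrix"}[on]
    return np.array([getattr(net, attr)[iu] for net in networks])


def group_edge_ttest(
    group_a: Sequence[IDSCN] | np.ndarray,
    group_b: Sequence[IDSCN] | np.ndarray,
    *,
    region_labels: Sequence[str] | None = None,
    variant: str = "pooled",
    alpha: float = 0.05,
    on: str = "z",
) -> pd.DataFrame:
    """Per-edge unpaired t-test between two groups of individualized
    networks.

    variant="pooled" is the classical equal-variance Student test;
    "welch" drops the equal-variance assumption. Returns one row per
    edge ordered by ascending p (ties broken lexicographically by region
    pair), with the Bonferroni threshold alpha / n_edges applied in the
    ``significant`` column. Edges with zero variance in both groups are
    flagged ``degenerate`` and assigned t=0, p=1.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if isinstance(group_a, np.ndarray):
        A = np.asarray(group_a, dtype=float)
        B = np.asarray(group_b, dtype=float)
    else:
        if region_labels is None:
            region_labels = group_a[0].region_labels
        A = stack_edge_vectors(list(group_a), on=on)
        B = stack_edge_vectors(list(group_b), on=on)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups disagree on edge count")
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least two subjects")
    n_edges = A.shape[1]
    if region_labels is not None:
        R = len(region_labels)
        if R * (R - 1) // 2 != n_edges:
            raise ValueError("region_labels inconsistent with edge count")
        iu = upper_triangle(R)
        names_i = [str(region_labels[i]) for i in iu[0]]
        names_j = [str(region_labels[j]) for j in iu[1]]
        idx_i, idx_j = iu[0], iu[1]
    else:
        idx_i = idx_j = np.arange(n_edges)
        names_i = [str(k) for k in range(n_edges)]
        names_j = names_i

    degenerate = (A.std(axis=0) == 0) & (B.std(axis=0) == 0) & (
        np.abs(A.mean(axis=0) - B.mean(axis=0)) < 1e-300
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=(variant == "pooled"))
    t = np.where(degenerate | ~np.isfinite(t), 0.0, t)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)

    threshold = alpha / n_edges
    df = pd.DataFrame({
        "region_i": names_i,
        "region_j": names_j,
        "index_i": idx_i,
        "index_j": idx_j,
        "mean_a": A.mean(axis=0),
        "mean_b": B.mean(axis=0),
        "t": t,
        "p": p,
        "p_threshold": threshold,
        "significant": p < threshold,
        "degenerate": degenerate,
    })
    df = df.sort_values(
        ["p", "index_i", "index_j"], kind="mergesort"
    ).reset_index(drop=True)
    return df


def edge_incidence(networks: Sequence[IDSCN]) -> pd.DataFrame:
    """Count, per edge, in how many subjects it is individually significant.

    Returns the edges that are significant in at least one subject, with
    the per-subject lists, ordered by descending count then region pair.
    """
    if not networks:
        raise ValueError("empty network list")
    labels = networks[0].region_labels
    for net in networks:
        if net.region_labels != labels:
            raise ValueError(
                f"region labels of subject {net.subject_id!r} differ from the group"
            )
    counts: dict[tuple[int, int], list[str]] = {}
    for net in networks:
        for edge in net.significant:
            counts.setdefault((edge.i, edge.j), []).append(net.subject_id)
    rows = [
        {
            "region_i": labels[i],
            "region_j": labels[j],
            "index_i": i,
            "index_j": j,
            "count": len(subjects),
            "subjects": ",".join(subjects),
        }
        for (i, j), subjects in counts.items()
    ]
    df = pd.DataFrame(
        rows, columns=["region_i", "region_j", "index_i", "index_j",
                       "count", "subjects"],
    )
    if len(df):
        df = df.sort_values(
            ["count", "index_i", "index_j"], ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df
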