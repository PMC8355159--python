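"""Clonal sharing between sorted B-cell subsets within one mouse.

Clones from different animals descend from independent recombination
events, so overlap is only meaningful within a mouse; cross-animal
aggregation averages matrices rather than pooling clones.  Presence
merges the two replicate libraries of each sorted sample by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .airr_io import SUBSETS
from .clones import CloneSet

__all__ = [
    "OverlapResult",
    "subset_presence",
    "jaccard_matrix",
    "cosine_matrix",
    "venn_counts",
    "presence_tracks",
    "compute_overlap",
]


def subset_presence(
    clone_set: CloneSet,
    mouse_id: str,
    subsets: list[str] | None = None,
    merge_replicates: bool = True,
) -> pd.DataFrame:
    """Clones x subsets copy-count table for one mouse.

    Rows are clone_ids present in the animal; a cell holds the summed
    copies of that clone's members in that subset (replicate libraries
    merged by default; ``merge_replicates=False`` restricts to library 1).
    """
    if subsets is None:
        subsets = [s for s in SUBSETS]
    rows: dict[int, dict[str, int]] = {}
    for clone in clone_set:
        for (mouse, subset, rep), copies in clone.presence.items():
            if mouse != mouse_id or subset not in subsets:
                continue
            if not merge_replicates and rep != 1:
                continue
            rows.setdefault(clone.clone_id, {s: 0 for s in subsets})
            rows[clone.clone_id][subset] += copies
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=subsets).fillna(0)
    return table.sort_index().astype(int)


def jaccard_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard similarity between subset clone sets.

    Entry (i, j) is the fraction of clones shared between the two
    subsets: |both| / |either|, each clone counted once per subset.  A
    subset with zero clones yields 0 entries with a warning.  The
    diagonal is reported as 1 (mask it for display scaling).
    """
    present = presence.to_numpy() > 0
    subsets = list(presence.columns)
    k = len(subsets)
    sizes = present.sum(axis=0)
    for s, size in zip(subsets, sizes):
        if size == 0:
            warnings.warn(f"subset {s!r} has zero clones; Jaccard entries set to 0")
    inter = present.T.astype(int) @ present.astype(int)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(jac, 1.0)
    return pd.DataFrame(jac, index=subsets, columns=subsets)


def cosine_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity between subset clone-abundance vectors.

    Clone size is taken into account: each subset is a nonnegative
    copy-count vector over the union clone axis, and entry (i, j) is
    dot(u_i, u_j) / (||u_i|| ||u_j||), in [0, 1].  Zero-norm subsets
    yield 0 entries with a warning.
    """
    mat = abundance.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("abundance counts must be nonnegative")
    subsets = list(abundance.columns)
    norms = np.linalg.norm(mat, axis=0)
    for s, nrm in zip(subsets, norms):
        if nrm == 0:
            warnings.warn(f"subset {s!r} has zero total abundance; cosine entries set to 0")
    dots = mat.T @ mat
    denom = norms[:, None] * norms[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(cos, np.where(norms > 0, 1.0, 0.0))
    return pd.DataFrame(cos, index=subsets, columns=subsets)


def venn_counts(presence: pd.DataFrame, subsets: list[str] | None = None) -> dict[str, int]:
    """Exact clone counts per subset-membership region.

    Regions partition the clones present in >= 1 of the chosen subsets
    (at most 6, i.e. 2^6 regions); keys join member subset names with
    ``"&"`` in the presence table's column order.
    """
    if subsets is not None:
        presence = presence[subsets]
    if presence.shape[1] > 6:
        raise ValueError("venn_counts supports at most 6 subsets")
    names = list(presence.columns)
    present = presence.to_numpy() > 0
    counts: dict[str, int] = {}
    for row in present:
        if not row.any():
            continue
        key = "&".join(n for n, p in zip(names, row) if p)
        counts[key] = counts.get(key, 0) + 1
    return counts


def presence_tracks(presence: pd.DataFrame, min_subsets: int = 2) -> tuple[pd.DataFrame, pd.Series]:
    """Clone-by-subset tracks for clones shared by >= ``min_subsets`` subsets.

    Rows order by (number of subsets descending, total copies
    descending, clone_id); the companion Series gives per-subset clone
    counts among the retained rows (the numbers printed along the right
    side of the track plot).
    """
    present = presence > 0
    n_subsets = present.sum(axis=1)
    keep = presence[n_subsets >= min_subsets]
    order = sorted(
        keep.index,
        key=lambda cid: (-int((keep.loc[cid] > 0).sum()), -int(keep.loc[cid].sum()), cid),
    )
    tracks = keep.loc[order]
    per_subset = (tracks > 0).sum(axis=0)
    return tracks, per_subset


@dataclass(slots=True)
class OverlapResult:
    """Within-mouse cross-subset overlap bundle."""

    mouse_id: str
    subsets: list[str]
    jaccard: pd.DataFrame
    cosine: pd.DataFrame
    venn_counts: dict[str, int]
    presence: pd.DataFrame


def compute_overlap(
    clone_set: CloneSet,
    mouse_id: str,
    subsets: list[str] | None = None,
    min_subsets: int = 2,
    merge_replicates: bool = True,
) -> OverlapResult:
    """Presence table plus Jaccard/cosine matrices and Venn counts for a mouse."""
    presence = subset_presence(clone_set, mouse_id, subsets=subsets, merge_replicates=merge_replicates)
    if presence.empty:
        raise ValueError(f"no clones found for mouse {mouse_id!r}")
    used = [s for s in presence.columns]
    return OverlapResult(
        mouse_id=mouse_id,
        subsets=used,
        jaccard=jaccard_matrix(presence),
        cosine=cosine_matrix(presence),
        venn_counts=venn_counts(presence),
        presence=presence,
    )
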