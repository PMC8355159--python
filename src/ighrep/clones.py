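"""Clone inference from annotated IgH rearrangements.

A clone is the set of rearrangements inferred to descend from one VDJ
recombination event.  Inference is two-stage:

1. Records are partitioned by (V gene, J gene, CDR3 nucleotide length)
   and, within each partition, single-linkage clustered at >= 85% CDR3
   amino-acid identity (connected components of the pairwise-identity
   graph at the threshold; a threshold cut of a single-linkage
   hierarchical clustering is exactly these components).
2. Clones whose copy-weighted consensus CDR3 nucleotide sequences lie
   within a Hamming distance of 2 are merged, *ignoring* V/J calls: this
   collapse absorbs spurious clones created by incorrect gene calls.
   Merging never crosses CDR3 lengths (Hamming distance is undefined
   there) and iterates to a fixed point so the operation is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .airr_io import SequenceRecord, translate_cdr3

__all__ = [
    "Clone",
    "CloneSet",
    "cdr3_identity",
    "cluster_partition",
    "consensus_cdr3",
    "collapse_clones",
    "call_clones",
]

#: Tie-break priority for consensus bases: concrete bases in alphabet
#: order, N last so it never wins a tie against a concrete base.
_BASE_PRIORITY = {b: i for i, b in enumerate("ACGTN")}

DEFAULT_IDENTITY = 0.85
DEFAULT_COLLAPSE_DIST = 2


@dataclass(slots=True)
class Clone:
    """An inferred clonal family of IgH rearrangements."""

    clone_id: int
    v_call: str
    j_call: str
    cdr3_len_nt: int
    consensus_cdr3_nt: str
    members: list[SequenceRecord]
    total_copies: int
    #: (mouse_id, subset, replicate) -> summed copies
    presence: dict[tuple[str, str, int], int]
    shm_percent_by_subset: dict[str, float] = field(default_factory=dict)

    def subset_copies(self, subset: str, strain: str | None = None, mouse_id: str | None = None) -> int:
        """Copies carried by members of this clone in one stratum."""
        return sum(
            r.copies
            for r in self.members
            if r.subset == subset
            and (strain is None or r.strain == strain)
            and (mouse_id is None or r.mouse_id == mouse_id)
        )

    def subsets(self, strain: str | None = None, mouse_id: str | None = None) -> set[str]:
        return {
            r.subset
            for r in self.members
            if (strain is None or r.strain == strain) and (mouse_id is None or r.mouse_id == mouse_id)
        }


@dataclass(slots=True)
class CloneSet:
    """All clones called for a cohort, with the parameters that made them."""

    clones: list[Clone]
    provenance: dict

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self):
        return iter(self.clones)

    @property
    def mouse_strains(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for clone in self.clones:
            for r in clone.members:
                out.setdefault(r.mouse_id, r.strain)
        return out

    def strata(self) -> list[tuple[str, str]]:
        """(strain, subset) combinations with at least one clone."""
        seen = {(r.strain, r.subset) for c in self.clones for r in c.members}
        return sorted(seen)

    def clones_in(self, strain: str | None = None, subset: str | None = None,
                  mouse_id: str | None = None) -> list[Clone]:
        out = []
        for c in self.clones:
            for r in c.members:
                if (
                    (strain is None or r.strain == strain)
                    and (subset is None or r.subset == subset)
                    and (mouse_id is None or r.mouse_id == mouse_id)
                ):
                    out.append(c)
                    break
        return out

    def clone_table(self) -> pd.DataFrame:
        """One row per clone; per-sample copy columns keyed mouse|subset|rep."""
        rows = []
        for c in self.clones:
            row = {
                "clone_id": c.clone_id,
                "v_call": c.v_call,
                "j_call": c.j_call,
                "cdr3_len_nt": c.cdr3_len_nt,
                "consensus_cdr3_nt": c.consensus_cdr3_nt,
                "total_copies": c.total_copies,
            }
            for (mouse, subset, rep), copies in sorted(c.presence.items()):
                row[f"{mouse}|{subset}|{rep}"] = copies
            rows.append(row)
        return pd.DataFrame(rows).fillna(0)

    def assignments(self) -> pd.DataFrame:
        """record_id -> clone_id mapping, one row per member record."""
        rows = [
            {"record_id": r.record_id, "clone_id": c.clone_id}
            for c in self.clones
            for r in c.members
        ]
        return pd.DataFrame(rows, columns=["record_id", "clone_id"])


def cdr3_identity(aa1: str, aa2: str) -> float:
    """Fraction of identical residues between two same-length CDR3s.

    Identity is only defined within a same-length partition; unequal
    lengths raise.  ``X`` (masked/ambiguous residue) matches only ``X``.
    """
    if len(aa1) != len(aa2):
        raise ValueError(f"CDR3 identity undefined for lengths {len(aa1)} != {len(aa2)}")
    if not aa1:
        raise ValueError("CDR3 identity undefined for empty strings")
    return sum(a == b for a, b in zip(aa1, aa2)) / len(aa1)


def _record_cdr3_aa(record: SequenceRecord) -> str:
    if record.cdr3_aa is not None:
        return record.cdr3_aa
    return translate_cdr3(record.cdr3_nt)


def _components(n: int, edges_i: list[int], edges_j: list[int]) -> np.ndarray:
    adj = csr_matrix((np.ones(len(edges_i), dtype=bool), (edges_i, edges_j)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_partition(
    records: list[SequenceRecord],
    threshold: float = DEFAULT_IDENTITY,
    linkage: str = "single",
) -> list[list[SequenceRecord]]:
    """Group same-(V, J, CDR3-length) records at >= ``threshold`` aa identity.

    Default single linkage takes the connected components of the graph
    with an edge wherever identity >= threshold (inclusive, "85%" read as
    a floor); ``linkage="complete"`` instead cuts a complete-linkage
    dendrogram at 1 - threshold.  Output ordering is canonical (groups
    and members sorted by (CDR3 nt, record_id)) so the result does not
    depend on input order.
    """
    if not records:
        return []
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    recs = sorted(records, key=lambda r: (r.cdr3_nt, r.record_id))
    n = len(recs)
    if len({(r.v_call, r.j_call, len(r.cdr3_nt)) for r in recs}) > 1:
        raise ValueError("cluster_partition requires records sharing (V, J, CDR3 length)")
    # identity on amino acids; out-of-frame partitions (length not a
    # multiple of 3) have no translation and fall back to nucleotides
    if len(recs[0].cdr3_nt) % 3 == 0:
        aa = [_record_cdr3_aa(r) for r in recs]
    else:
        aa = [r.cdr3_nt for r in recs]

    # pairwise identity on a small uint8 matrix; partitions are small
    mat = np.frombuffer("".join(aa).encode(), dtype=np.uint8).reshape(n, len(aa[0]))
    ident = (mat[:, None, :] == mat[None, :, :]).mean(axis=2)
    if linkage == "single":
        ii, jj = np.nonzero(ident >= threshold - 1e-12)
        labels = _components(n, list(ii), list(jj))
    elif linkage == "complete":
        from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        if n == 1:
            labels = np.zeros(1, dtype=int)
        else:
            dist = 1.0 - ident
            np.fill_diagonal(dist, 0.0)
            z = scipy_linkage(squareform(dist, checks=False), method="complete")
            labels = fcluster(z, t=(1.0 - threshold) + 1e-12, criterion="distance")
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    groups: dict[int, list[SequenceRecord]] = {}
    for lab, rec in zip(labels, recs):
        groups.setdefault(int(lab), []).append(rec)
    return sorted(groups.values(), key=lambda g: (g[0].cdr3_nt, g[0].record_id))


def consensus_cdr3(group: list[SequenceRecord]) -> str:
    """Copy-weighted per-position majority CDR3 nucleotide sequence.

    Ties break by fixed alphabet order A < C < G < T; ``N`` never wins a
    tie against a concrete base.
    """
    if not group:
        raise ValueError("consensus of empty group is undefined")
    length = len(group[0].cdr3_nt)
    if any(len(r.cdr3_nt) != length for r in group):
        raise ValueError("consensus requires equal CDR3 lengths")
    out = []
    for pos in range(length):
        weight: dict[str, int] = {}
        for r in group:
            base = r.cdr3_nt[pos]
            weight[base] = weight.get(base, 0) + r.copies
        out.append(min(weight, key=lambda b: (-weight[b], _BASE_PRIORITY[b])))
    return "".join(out)


def _make_clone(clone_id: int, members: list[SequenceRecord]) -> Clone:
    presence: dict[tuple[str, str, int], int] = {}
    for r in members:
        key = (r.mouse_id, r.subset, r.replicate)
        presence[key] = presence.get(key, 0) + r.copies
    return Clone(
        clone_id=clone_id,
        v_call=members[0].v_call,
        j_call=members[0].j_call,
        cdr3_len_nt=len(members[0].cdr3_nt),
        consensus_cdr3_nt=consensus_cdr3(members),
        members=members,
        total_copies=sum(r.copies for r in members),
        presence=presence,
    )


def _hamming_le(consensi: list[str], max_dist: int) -> tuple[list[int], list[int]]:
    """Index pairs of equal-length strings at Hamming distance <= max_dist."""
    n = len(consensi)
    mat = np.frombuffer("".join(consensi).encode(), dtype=np.uint8).reshape(n, len(consensi[0]))
    dist = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    ii, jj = np.nonzero(dist <= max_dist)
    return list(ii), list(jj)


def collapse_clones(clones: list[Clone], max_nt_dist: int = DEFAULT_COLLAPSE_DIST) -> list[Clone]:
    """Merge clones whose consensus CDR3s are within ``max_nt_dist`` nt.

    Merging is transitive (connected components), ignores V/J calls —
    it exists to absorb incorrect gene calls — and never crosses CDR3
    lengths.  The merged clone takes its V/J calls from the pre-merge
    clone with the largest total_copies (ties to the smaller clone_id)
    and its consensus is recomputed from the pooled members.  The merge
    repeats until no consensus pair is within range, so a second call is
    a no-op.
    """
    current = list(clones)
    while True:
        by_len: dict[int, list[Clone]] = {}
        for c in current:
            by_len.setdefault(c.cdr3_len_nt, []).append(c)
        merged: list[Clone] = []
        changed = False
        for length_group in by_len.values():
            group = sorted(length_group, key=lambda c: c.clone_id)
            ii, jj = _hamming_le([c.consensus_cdr3_nt for c in group], max_nt_dist)
            labels = _components(len(group), ii, jj)
            comps: dict[int, list[Clone]] = {}
            for lab, c in zip(labels, group):
                comps.setdefault(int(lab), []).append(c)
            for comp in comps.values():
                if len(comp) == 1:
                    merged.append(comp[0])
                    continue
                changed = True
                dominant = min(comp, key=lambda c: (-c.total_copies, c.clone_id))
                members = [r for c in comp for r in c.members]
                clone = _make_clone(dominant.clone_id, members)
                clone.v_call = dominant.v_call
                clone.j_call = dominant.j_call
                merged.append(clone)
        current = merged
        if not changed:
            break
    return _renumber(current)


def _renumber(clones: list[Clone]) -> list[Clone]:
    """Deterministic clone ids: descending total_copies, then consensus."""
    ordered = sorted(clones, key=lambda c: (-c.total_copies, c.consensus_cdr3_nt, c.v_call, c.j_call))
    for i, c in enumerate(ordered, start=1):
        c.clone_id = i
    return ordered


def call_clones(
    records: list[SequenceRecord],
    threshold: float = DEFAULT_IDENTITY,
    max_nt_dist: int = DEFAULT_COLLAPSE_DIST,
    linkage: str = "single",
    collapse: bool = True,
) -> CloneSet:
    """End-to-end clone inference: partition, cluster, consensus, collapse.

    Every input record lands in exactly one clone; total copies are
    conserved; the result is invariant to input order up to clone_id
    labels (which are themselves canonical).
    """
    partitions: dict[tuple[str, str, int], list[SequenceRecord]] = {}
    for r in records:
        partitions.setdefault((r.v_call, r.j_call, len(r.cdr3_nt)), []).append(r)

    clones: list[Clone] = []
    for key in sorted(partitions):
        for group in cluster_partition(partitions[key], threshold=threshold, linkage=linkage):
            clones.append(_make_clone(len(clones) + 1, group))
    if collapse:
        clones = collapse_clones(clones, max_nt_dist=max_nt_dist)
    else:
        clones = _renumber(clones)
    return CloneSet(
        clones=clones,
        provenance={
            "identity_threshold": threshold,
            "collapse_max_nt_dist": max_nt_dist if collapse else None,
            "linkage": linkage,
            "n_records": len(records),
        },
    )
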