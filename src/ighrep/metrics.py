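"""Per-subset repertoire summary statistics.

Covers the clonality index D20 (fraction of sequence copies carried by
the 20 largest clones), replicate-library Jaccard overlap (clone
resampling between the two sequencing libraries of a sorted sample, an
independent proxy for clone size), somatic hypermutation (fraction of
clones whose V segment is mutated relative to germline), CDR3-length
distributions, and top-VH usage matrices.  Each clone counts once per
(strain, subset) stratum; when a clone spans several subsets its SHM is
recomputed from the sequences of each subset alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .airr_io import GermlineSet, SequenceRecord
from .clones import Clone, CloneSet

__all__ = [
    "d20_index",
    "replicate_jaccard",
    "replicate_jaccard_table",
    "clone_mutation_percent",
    "shm_fraction",
    "shm_table",
    "d20_table",
    "cdr3_length_distribution",
    "vh_usage_matrix",
    "VhUsage",
]

DEFAULT_TOP_CLONES = 20
DEFAULT_MUTATED_THRESHOLD = 1.0  # percent of compared V positions


def d20_index(clone_copies: list[int] | np.ndarray, top_n: int = DEFAULT_TOP_CLONES) -> float:
    """Fraction of total copies contributed by the ``top_n`` largest clones.

    Copies are sorted descending (stable, so rank-boundary ties resolve
    by input position) and the top ``min(top_n, n)`` summed over the
    total; a repertoire of <= ``top_n`` clones scores 1.0.
    """
    copies = np.asarray(clone_copies)
    if copies.size == 0:
        raise ValueError("d20_index of an empty repertoire is undefined")
    if (copies < 1).any():
        raise ValueError("clone copy counts must be >= 1")
    top = np.sort(copies, kind="stable")[::-1][:top_n]
    return float(top.sum() / copies.sum())


def replicate_jaccard(clone_ids_rep1: set, clone_ids_rep2: set) -> float:
    """Jaccard index of the clone sets of a sample's two libraries.

    Each clone counts once (no weighting for clone size).  Two empty
    sets are defined as 0 with a warning.
    """
    union = clone_ids_rep1 | clone_ids_rep2
    if not union:
        warnings.warn("replicate_jaccard of two empty clone sets; defined as 0")
        return 0.0
    return len(clone_ids_rep1 & clone_ids_rep2) / len(union)


def replicate_jaccard_table(clone_set: CloneSet) -> pd.DataFrame:
    """Per (strain, mouse, subset) Jaccard between replicate libraries 1 and 2."""
    presence: dict[tuple[str, str, str], dict[int, set[int]]] = {}
    strains = clone_set.mouse_strains
    for clone in clone_set:
        for (mouse, subset, rep), _ in clone.presence.items():
            key = (strains[mouse], mouse, subset)
            presence.setdefault(key, {}).setdefault(rep, set()).add(clone.clone_id)
    rows = []
    for (strain, mouse, subset), reps in sorted(presence.items()):
        rows.append(
            {
                "strain": strain,
                "mouse_id": mouse,
                "subset": subset,
                "jaccard": replicate_jaccard(reps.get(1, set()), reps.get(2, set())),
            }
        )
    return pd.DataFrame(rows, columns=["strain", "mouse_id", "subset", "jaccard"])


def _member_mutation_percent(record: SequenceRecord, germlines: GermlineSet) -> float | None:
    """Percent mutated V positions for one record, or None if unresolvable."""
    if record.v_mutation_count is not None:
        germ = germlines.v_segments.get(record.v_call)
        if germ is None:
            return None
        return 100.0 * record.v_mutation_count / len(germ)
    if record.v_observed_nt is not None:
        germ = germlines.v_segments.get(record.v_call)
        if germ is None:
            return None
        obs = record.v_observed_nt
        ref = germ[: len(obs)]
        pairs = [(o, g) for o, g in zip(obs, ref) if o != "N" and g != "N"]
        if not pairs:
            return None
        mutated = sum(o != g for o, g in pairs)
        return 100.0 * mutated / len(pairs)
    return None


def clone_mutation_percent(
    clone: Clone,
    subset: str,
    germlines: GermlineSet,
    strain: str | None = None,
    mouse_id: str | None = None,
) -> float:
    """Copy-weighted mean percent of mutated V positions, subset members only.

    A clone spanning several subsets gets a separate value per subset,
    computed just from the sequences observed in that subset.  Mutations
    come from ``v_mutation_count`` when present, otherwise from the
    Hamming distance between the germline-aligned V segment and its
    germline slice (N positions excluded from the comparison).
    """
    num = 0.0
    weight = 0
    seen = False
    for r in clone.members:
        if r.subset != subset:
            continue
        if strain is not None and r.strain != strain:
            continue
        if mouse_id is not None and r.mouse_id != mouse_id:
            continue
        seen = True
        pct = _member_mutation_percent(r, germlines)
        if pct is None:
            continue
        num += pct * r.copies
        weight += r.copies
    if not seen:
        raise ValueError(f"clone {clone.clone_id} has no members in subset {subset!r}")
    if weight == 0:
        raise ValueError(
            f"clone {clone.clone_id}: no member in subset {subset!r} resolves V mutations"
        )
    return num / weight


def shm_fraction(
    clone_set: CloneSet,
    strain: str,
    subset: str,
    germlines: GermlineSet,
    mutated_threshold_percent: float = DEFAULT_MUTATED_THRESHOLD,
    weighted: bool = False,
) -> float:
    """Fraction of a stratum's clones carrying somatic hypermutation.

    A clone is "mutated" when its per-subset mutation percent is >= the
    threshold (default 1% of compared V positions, buffering sequencing
    error); a threshold of 0 means the strict reading: any clone with
    > 0 mutations counts.  Unweighted: each clone counts once.
    Weighted: each clone contributes its subset copy count to both
    numerator and denominator.
    """
    clones = clone_set.clones_in(strain=strain, subset=subset)
    if not clones:
        raise ValueError(f"no clones in stratum ({strain!r}, {subset!r})")
    num = 0.0
    den = 0.0
    for clone in clones:
        pct = clone_mutation_percent(clone, subset, germlines, strain=strain)
        clone.shm_percent_by_subset[subset] = pct
        w = clone.subset_copies(subset, strain=strain) if weighted else 1
        den += w
        mutated = pct > 0 if mutated_threshold_percent == 0 else pct >= mutated_threshold_percent
        if mutated:
            num += w
    return num / den


def shm_table(
    clone_set: CloneSet,
    germlines: GermlineSet,
    mutated_threshold_percent: float = DEFAULT_MUTATED_THRESHOLD,
) -> pd.DataFrame:
    """SHM fraction (both weightings) for every (strain, subset) stratum."""
    rows = []
    for strain, subset in clone_set.strata():
        rows.append(
            {
                "strain": strain,
                "subset": subset,
                "n_clones": len(clone_set.clones_in(strain=strain, subset=subset)),
                "shm_fraction_unweighted": shm_fraction(
                    clone_set, strain, subset, germlines,
                    mutated_threshold_percent=mutated_threshold_percent, weighted=False,
                ),
                "shm_fraction_weighted": shm_fraction(
                    clone_set, strain, subset, germlines,
                    mutated_threshold_percent=mutated_threshold_percent, weighted=True,
                ),
            }
        )
    return pd.DataFrame(rows)


def d20_table(clone_set: CloneSet, top_n: int = DEFAULT_TOP_CLONES) -> pd.DataFrame:
    """D20 per (strain, mouse, subset): one value per animal per population."""
    strains = clone_set.mouse_strains
    copies: dict[tuple[str, str, str], dict[int, int]] = {}
    for clone in clone_set:
        for (mouse, subset, _rep), n in clone.presence.items():
            key = (strains[mouse], mouse, subset)
            copies.setdefault(key, {})
            copies[key][clone.clone_id] = copies[key].get(clone.clone_id, 0) + n
    rows = []
    for (strain, mouse, subset), per_clone in sorted(copies.items()):
        rows.append(
            {
                "strain": strain,
                "mouse_id": mouse,
                "subset": subset,
                "n_clones": len(per_clone),
                "d20": d20_index(list(per_clone.values()), top_n=top_n),
            }
        )
    return pd.DataFrame(rows, columns=["strain", "mouse_id", "subset", "n_clones", "d20"])


def cdr3_length_distribution(clone_set: CloneSet, strain: str, subset: str) -> np.ndarray:
    """CDR3 nucleotide lengths, one entry per clone present in the stratum."""
    return np.array(
        sorted(c.cdr3_len_nt for c in clone_set.clones_in(strain=strain, subset=subset)),
        dtype=int,
    )


@dataclass(slots=True)
class VhUsage:
    """Raw and row-normalized VH usage (genes x (strain, subset) strata)."""

    raw: pd.DataFrame
    normalized: pd.DataFrame
    constant_rows: list[str]


def vh_usage_matrix(clone_set: CloneSet, top_n: int = DEFAULT_TOP_CLONES) -> VhUsage:
    """Clone counts per VH gene per stratum for the ``top_n`` most used genes.

    Each clone counts once per stratum.  Genes rank by total clone count
    (lexicographic tie-break).  Rows are min-max normalized to [0, 1];
    constant rows (no dynamic range) map to all-0 and are flagged.
    """
    if not clone_set.clones:
        raise ValueError("vh_usage_matrix needs at least one clone")
    counts: dict[str, dict[tuple[str, str], int]] = {}
    for strain, subset in clone_set.strata():
        for clone in clone_set.clones_in(strain=strain, subset=subset):
            counts.setdefault(clone.v_call, {})
            counts[clone.v_call][(strain, subset)] = counts[clone.v_call].get((strain, subset), 0) + 1
    raw = pd.DataFrame(counts).T.fillna(0).astype(int)
    raw.columns = pd.MultiIndex.from_tuples(raw.columns, names=["strain", "subset"])
    raw = raw.sort_index(axis=1)
    totals = raw.sum(axis=1)
    if len(raw) < top_n:
        warnings.warn(f"only {len(raw)} distinct VH genes for top_n={top_n}; returning all")
    order = sorted(raw.index, key=lambda g: (-totals[g], g))[:top_n]
    raw = raw.loc[order]

    span = raw.max(axis=1) - raw.min(axis=1)
    constant = list(raw.index[span == 0])
    safe_span = span.replace(0, 1)
    normalized = raw.sub(raw.min(axis=1), axis=0).div(safe_span, axis=0)
    normalized.loc[constant] = 0.0
    return VhUsage(raw=raw, normalized=normalized, constant_rows=constant)
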