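"""Shared fixtures: record factories, random clustering instances, and a
brute-force clone-calling oracle kept independent of the implementation."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from ighrep import SequenceRecord, SimConfig, call_clones, simulate

_COUNTER = {"n": 0}


def make_record(
    cdr3_nt: str = "TGTGCTAGATGG",
    cdr3_aa: str | None = None,
    v_call: str = "IGHV1-1",
    j_call: str = "IGHJ1",
    subset: str = "FoB",
    mouse_id: str = "WT-m1",
    strain: str = "WT",
    replicate: int = 1,
    copies: int = 1,
    record_id: str | None = None,
    **kwargs,
) -> SequenceRecord:
    if record_id is None:
        _COUNTER["n"] += 1
        record_id = f"t{_COUNTER['n']:05d}"
    return SequenceRecord(
        record_id=record_id,
        mouse_id=mouse_id,
        strain=strain,
        subset=subset,
        replicate=replicate,
        v_call=v_call,
        j_call=j_call,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        copies=copies,
        **kwargs,
    )


def random_instance(rng: np.random.Generator, n_max: int = 12) -> list[SequenceRecord]:
    """Small random record sets with deliberate near-threshold structure:
    few founders per (V, J, length) cell, members mutated by 0-3 nt so
    both the identity clustering and the 2-nt collapse have work to do."""
    n_rec = int(rng.integers(1, n_max + 1))
    founders = []
    for _ in range(int(rng.integers(1, 4))):
        aa_len = int(rng.integers(4, 7))
        nt = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3 * aa_len))
        founders.append(
            (f"IGHV1-{rng.integers(1, 3)}", f"IGHJ{rng.integers(1, 3)}", nt)
        )
    records = []
    for _ in range(n_rec):
        v, j, nt = founders[rng.integers(0, len(founders))]
        chars = list(nt)
        for pos in rng.choice(len(chars), size=int(rng.integers(0, 4)), replace=False):
            chars[pos] = "ACGT"[rng.integers(0, 4)]
        mutated = "".join(chars)
        records.append(
            make_record(
                cdr3_nt=mutated,
                cdr3_aa=str(Seq(mutated).translate()),
                v_call=v,
                j_call=j,
                copies=int(rng.integers(1, 6)),
                subset=("FoB", "ABC")[rng.integers(0, 2)],
                replicate=int(rng.integers(1, 3)),
            )
        )
    return records


# ---------------------------------------------------------------- oracle

def _bfs_components(n: int, adjacent) -> list[list[int]]:
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in range(n):
                if not seen[j] and adjacent(i, j):
                    seen[j] = True
                    stack.append(j)
        comps.append(comp)
    return comps


def _oracle_consensus(members: list[SequenceRecord]) -> str:
    length = len(members[0].cdr3_nt)
    out = []
    for pos in range(length):
        votes: Counter = Counter()
        for r in members:
            votes[r.cdr3_nt[pos]] += r.copies
        best = sorted(votes.items(), key=lambda kv: (-kv[1], "ACGTN".index(kv[0])))[0][0]
        out.append(best)
    return "".join(out)


def oracle_call(
    records: list[SequenceRecord], threshold: float = 0.85, max_nt_dist: int = 2
) -> set[frozenset]:
    """All-pairs brute-force clone calling: identity graph components per
    (V, J, CDR3-length) cell, then repeated consensus-Hamming merges."""

    def aa(r: SequenceRecord) -> str:
        return r.cdr3_aa if r.cdr3_aa is not None else str(Seq(r.cdr3_nt).translate())

    def identity(a: SequenceRecord, b: SequenceRecord) -> float:
        x, y = aa(a), aa(b)
        return sum(p == q for p, q in zip(x, y)) / len(x)

    def linked(i: int, j: int) -> bool:
        a, b = records[i], records[j]
        if (a.v_call, a.j_call, len(a.cdr3_nt)) != (b.v_call, b.j_call, len(b.cdr3_nt)):
            return False
        return identity(a, b) >= threshold

    groups = [[records[i] for i in comp] for comp in _bfs_components(len(records), linked)]

    while True:
        consensi = [_oracle_consensus(g) for g in groups]

        def near(i: int, j: int) -> bool:
            a, b = consensi[i], consensi[j]
            return len(a) == len(b) and sum(p != q for p, q in zip(a, b)) <= max_nt_dist

        comps = _bfs_components(len(groups), near)
        if all(len(c) == 1 for c in comps):
            break
        groups = [[r for gi in comp for r in groups[gi]] for comp in comps]
    return {frozenset(r.record_id for r in g) for g in groups}


def partition_of(clone_set) -> set[frozenset]:
    return {frozenset(r.record_id for r in c.members) for c in clone_set}


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_cohort():
    """One simulated mouse with the default gradient, plus its clone calls."""
    cfg = SimConfig(seed=11, strains=("DKO-F",), n_mice_per_strain=1)
    records, truth, germlines = simulate(cfg)
    clone_set = call_clones(records)
    return records, truth, germlines, clone_set
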