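"""Repertoire summary statistics: D20, replicate Jaccard, SHM, CDR3, VH usage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ighrep import (
    GermlineSet,
    call_clones,
    cdr3_length_distribution,
    clone_mutation_percent,
    d20_index,
    d20_table,
    replicate_jaccard,
    replicate_jaccard_table,
    shm_fraction,
    vh_usage_matrix,
)
from ighrep.clones import _make_clone

from conftest import make_record


class TestD20Index:
    def test_all_clones_count_when_fewer_than_twenty(self):
        assert d20_index([5] * 15) == 1.0

    def test_uniform_hundred_clones(self):
        assert d20_index([1] * 100) == pytest.approx(0.2)

    def test_skewed_forty_clone_repertoire(self):
        copies = [50] + [10] * 9 + [1] * 30
        assert d20_index(copies) == pytest.approx(150 / 170)

    def test_empty_repertoire_raises(self):
        with pytest.raises(ValueError):
            d20_index([])

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_permutation_invariant_and_bounded(self, copies):
        rng = np.random.default_rng(0)
        shuffled = list(copies)
        rng.shuffle(shuffled)
        assert d20_index(shuffled) == pytest.approx(d20_index(copies))
        assert 0 < d20_index(copies) <= 1

    def test_transferring_mass_into_the_top_twenty_never_decreases_d20(self):
        copies = [30] * 20 + [5] * 10
        moved = [31] + [30] * 19 + [4] + [5] * 9  # one copy from rank-21 to rank-1
        assert d20_index(moved) >= d20_index(copies)


class TestReplicateJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
        ],
    )
    def test_set_overlap(self, a, b, expected):
        assert replicate_jaccard(a, b) == pytest.approx(expected)

    def test_two_empty_sets_warn_and_define_zero(self):
        with pytest.warns(UserWarning):
            assert replicate_jaccard(set(), set()) == 0.0

    def test_symmetry_and_identity_condition(self):
        a, b = {1, 2, 3}, {2, 3, 4}
        assert replicate_jaccard(a, b) == replicate_jaccard(b, a)
        assert replicate_jaccard(a, a) == 1.0

    def test_table_splits_by_replicate_library(self):
        records = [
            make_record(cdr3_nt="TGTAAAAAATGG", replicate=1),
            make_record(cdr3_nt="TGTAAAAAATGG", replicate=2),
            make_record(cdr3_nt="TGTCCCCCCTGG", v_call="IGHV3-3", replicate=1),
        ]
        table = replicate_jaccard_table(call_clones(records))
        assert table.loc[0, "jaccard"] == pytest.approx(0.5)


def _germ(length=300):
    return GermlineSet(v_segments={"IGHV1-1": "A" * length}, j_segments={"IGHJ1": "ACGT"})


def _mutated_v(n_mut, length=300):
    return "G" * n_mut + "A" * (length - n_mut)


class TestCloneMutationPercent:
    def test_germline_identical_members_have_zero(self):
        clone = _make_clone(1, [make_record(v_observed_nt=_mutated_v(0))])
        assert clone_mutation_percent(clone, "FoB", _germ()) == 0.0

    def test_three_mutations_over_three_hundred_positions(self):
        clone = _make_clone(1, [make_record(v_observed_nt=_mutated_v(3))])
        assert clone_mutation_percent(clone, "FoB", _germ()) == pytest.approx(1.0)

    def test_copy_weighted_mean_across_members(self):
        clone = _make_clone(
            1,
            [
                make_record(v_observed_nt=_mutated_v(6), copies=3),   # 2%
                make_record(v_observed_nt=_mutated_v(15), copies=1),  # 5%
            ],
        )
        assert clone_mutation_percent(clone, "FoB", _germ()) == pytest.approx(2.75)

    def test_mutation_count_field_is_an_equivalent_source(self):
        clone = _make_clone(1, [make_record(v_mutation_count=3)])
        assert clone_mutation_percent(clone, "FoB", _germ()) == pytest.approx(1.0)

    def test_subset_restriction_uses_only_that_subsets_sequences(self):
        clone = _make_clone(
            1,
            [
                make_record(v_observed_nt=_mutated_v(0), subset="FoB"),
                make_record(v_observed_nt=_mutated_v(30), subset="GCB_CD11cpos"),
            ],
        )
        assert clone_mutation_percent(clone, "FoB", _germ()) == 0.0
        assert clone_mutation_percent(clone, "GCB_CD11cpos", _germ()) == pytest.approx(10.0)

    def test_unresolvable_clone_raises_with_its_id(self):
        clone = _make_clone(7, [make_record()])
        with pytest.raises(ValueError, match="7"):
            clone_mutation_percent(clone, "FoB", _germ())


def _shm_clone_set():
    """Four single-clone families with mutation % {0, 0.5, 2, 3} over a
    200-nt V and subset copies {10, 10, 1, 1}; distinct CDR3s keep them
    separate."""
    specs = [(0, 10, "TGTAAAAAATGG"), (1, 10, "TGTCCCCCCTGG"),
             (4, 1, "TGTGGGGGGTGG"), (6, 1, "TGTTTTTTTTGG")]
    records = [
        make_record(cdr3_nt=cdr3, copies=copies, v_observed_nt=_mutated_v(nmut, length=200),
                    v_call=f"IGHV{i + 1}-1")
        for i, (nmut, copies, cdr3) in enumerate(specs)
    ]
    return call_clones(records)


_GERM200 = GermlineSet(v_segments={f"IGHV{i}-1": "A" * 200 for i in range(1, 5)},
                       j_segments={"IGHJ1": "ACGT"})


class TestShmFraction:
    def test_all_unmutated_is_zero_for_both_weightings(self):
        records = [
            make_record(cdr3_nt="TGTAAAAAATGG", v_observed_nt=_mutated_v(0, 200)),
            make_record(cdr3_nt="TGTCCCCCCTGG", v_observed_nt=_mutated_v(0, 200), v_call="IGHV2-1"),
        ]
        cs = call_clones(records)
        for weighted in (False, True):
            assert shm_fraction(cs, "WT", "FoB", _GERM200, weighted=weighted) == 0.0

    def test_enumerated_mixture_unweighted_and_weighted(self):
        cs = _shm_clone_set()
        assert shm_fraction(cs, "WT", "FoB", _GERM200, weighted=False) == pytest.approx(0.5)
        assert shm_fraction(cs, "WT", "FoB", _GERM200, weighted=True) == pytest.approx(2 / 22)

    def test_zero_threshold_counts_any_mutated_clone(self):
        cs = _shm_clone_set()
        frac = shm_fraction(cs, "WT", "FoB", _GERM200, mutated_threshold_percent=0.0)
        assert frac == pytest.approx(3 / 4)

    def test_weightings_coincide_for_equal_copy_clones(self):
        records = [
            make_record(cdr3_nt="TGTAAAAAATGG", copies=4, v_observed_nt=_mutated_v(9, 200)),
            make_record(cdr3_nt="TGTCCCCCCTGG", copies=4, v_observed_nt=_mutated_v(0, 200), v_call="IGHV2-1"),
        ]
        cs = call_clones(records)
        assert shm_fraction(cs, "WT", "FoB", _GERM200, weighted=False) == pytest.approx(
            shm_fraction(cs, "WT", "FoB", _GERM200, weighted=True)
        )

    def test_empty_stratum_raises(self):
        with pytest.raises(ValueError, match="stratum"):
            shm_fraction(_shm_clone_set(), "WT", "ABC", _GERM200)


class TestCdr3LengthDistribution:
    def test_clone_counts_once_per_subset_it_occupies(self):
        records = [
            make_record(cdr3_nt="TGTAAAAAAAAAAAAAAAAAAAAAAAATGG", subset="FoB"),
            make_record(cdr3_nt="TGTAAAAAAAAAAAAAAAAAAAAAAAATGG", subset="ABC"),
        ]
        cs = call_clones(records)
        assert len(cs) == 1
        assert list(cdr3_length_distribution(cs, "WT", "FoB")) == [30]
        assert list(cdr3_length_distribution(cs, "WT", "ABC")) == [30]

    def test_empty_stratum_is_empty(self):
        cs = call_clones([make_record(cdr3_nt="TGTGCTAGA")])
        assert cdr3_length_distribution(cs, "WT", "ABC").size == 0

    def test_three_clone_length_multiset(self):
        records = [
            make_record(cdr3_nt="T" * 30, cdr3_aa="K" * 10),
            make_record(cdr3_nt="A" * 33, cdr3_aa="K" * 11),
            make_record(cdr3_nt="C" * 45, cdr3_aa="K" * 15),
        ]
        cs = call_clones(records)
        lengths = cdr3_length_distribution(cs, "WT", "FoB")
        assert sorted(lengths) == [30, 33, 45]
        assert np.median(lengths) == 33


class TestVhUsage:
    def _cs(self, gene_strata):
        """gene_strata: list of (v_gene, subset, n_clones); clones get
        pairwise-distinct CDR3 lengths so none co-cluster."""
        records = []
        for gene, subset, n in gene_strata:
            for k in range(n):
                aa_len = 5 + k
                records.append(
                    make_record(cdr3_nt="AAA" * aa_len, cdr3_aa="K" * aa_len,
                                v_call=gene, subset=subset)
                )
        return call_clones(records, collapse=False)

    def test_min_max_row_normalization(self):
        cs = self._cs([("IGHV1-1", "FoB", 2), ("IGHV1-1", "ABC", 6), ("IGHV1-1", "GCB_CD11cpos", 10)])
        with pytest.warns(UserWarning):
            usage = vh_usage_matrix(cs, top_n=20)
        row = usage.normalized.loc["IGHV1-1"]
        assert sorted(row.values) == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_row_maps_to_zero_and_is_flagged(self):
        cs = self._cs([("IGHV1-1", "FoB", 4), ("IGHV1-1", "ABC", 4)])
        with pytest.warns(UserWarning):
            usage = vh_usage_matrix(cs, top_n=20)
        assert usage.constant_rows == ["IGHV1-1"]
        assert (usage.normalized.loc["IGHV1-1"] == 0).all()

    def test_top_n_selection_by_total_clone_count(self):
        strata = [(f"IGHV1-{i}", "FoB", 25 - i) for i in range(1, 26)]
        cs = self._cs(strata)
        usage = vh_usage_matrix(cs, top_n=20)
        assert len(usage.raw) == 20
        assert "IGHV1-1" in usage.raw.index and "IGHV1-25" not in usage.raw.index


def test_d20_table_reports_one_row_per_animal_subset(small_cohort):
    _, _, _, clone_set = small_cohort
    table = d20_table(clone_set)
    assert set(table.columns) == {"strain", "mouse_id", "subset", "n_clones", "d20"}
    assert table["d20"].between(0, 1).all()
    assert len(table) == 6  # one mouse, six sorted subsets
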