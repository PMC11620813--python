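"""Descriptive profiles, knowledge scores, and group comparisons."""

from __future__ import annotations

import numpy as np
import pytest

from ethnoquant import (
    DegenerateStratificationError,
    EmptyInputError,
    InformantRecord,
    ailment_species_counts,
    categorical_profile,
    compare_groups,
    knowledge_scores,
)

from conftest import make_dataset, random_dataset


def pct(profile, category):
    return round(profile[category] / profile.denominator * 100, 1)


# ---------------------------------------------------------------------------
# categorical profiles
# ---------------------------------------------------------------------------

def test_life_form_profile_matches_survey(urambo_dataset):
    prof = categorical_profile(urambo_dataset, "life_form")
    assert prof.counts == (("tree", 26), ("herb", 10), ("shrub", 6))
    assert pct(prof, "tree") == 61.9
    assert pct(prof, "herb") == 23.8
    assert pct(prof, "shrub") == 14.3


def test_origin_profile_matches_survey(urambo_dataset):
    prof = categorical_profile(urambo_dataset, "origin")
    assert prof["native"] == 28 and prof["introduced"] == 14
    assert pct(prof, "native") == 66.7


def test_source_profile_matches_survey(urambo_dataset):
    prof = categorical_profile(urambo_dataset, "source")
    assert prof["wild"] == 19 and prof["both"] == 15 and prof["cultivated"] == 8
    assert pct(prof, "wild") == 45.2
    assert pct(prof, "both") == 35.7
    # 8/42 = 19.05%; the survey text prints 19.1 (the count, 8, is the anchor)
    assert pct(prof, "cultivated") == 19.0


def test_iucn_profile_matches_survey(urambo_dataset):
    prof = categorical_profile(urambo_dataset, "iucn_category")
    assert dict(prof.counts) == {"LC": 23, "NoRecord": 15, "DD": 3, "EN": 1}
    assert pct(prof, "LC") == 54.8
    assert pct(prof, "NoRecord") == 35.7
    assert pct(prof, "DD") == 7.1
    assert pct(prof, "EN") == 2.4


def test_single_species_profile_is_total():
    ds = make_dataset([], 1, 1)  # one tree species
    prof = categorical_profile(ds, "life_form")
    assert prof.counts == (("tree", 1),)
    assert pct(prof, "tree") == 100.0


def test_unknown_attribute_lists_valid_ones(urambo_dataset):
    with pytest.raises(ValueError) as err:
        categorical_profile(urambo_dataset, "height")
    assert "life_form" in str(err.value)


def test_report_attribute_profile_needs_reports(urambo_dataset):
    with pytest.raises(EmptyInputError):
        categorical_profile(urambo_dataset, "preparation")
    ds = make_dataset([(0, 0, "cough", "leaf"), (1, 0, "flu", "leaf")], 2, 1)
    prof = categorical_profile(ds, "preparation")
    assert prof.counts == (("decoction", 2),)
    assert prof.denominator == 2


# ---------------------------------------------------------------------------
# ailment species counts
# ---------------------------------------------------------------------------

def test_ailment_species_counts_match_consensus_table(urambo):
    counts = ailment_species_counts(urambo.dataset, source="plants")
    expected = dict(zip(urambo.category_counts["category"], urambo.category_counts["Nt"]))
    assert counts == expected
    assert counts["cough"] == 29
    assert counts["asthma"] == 10


def test_ailment_species_counts_empty_dataset():
    ds = make_dataset([], 0, 0)
    counts = ailment_species_counts(ds)
    assert all(v == 0 for v in counts.values())


# ---------------------------------------------------------------------------
# knowledge scores
# ---------------------------------------------------------------------------

def test_knowledge_score_counts_distinct_species():
    tuples = [(0, s, "cough", "leaf") for s in range(5)]
    tuples += [(0, s, "flu", "leaf") for s in range(4)]  # repeats of same species
    tuples += [(0, 5, "flu", "bark")]
    ds = make_dataset(tuples, 2, 6)
    scores = {s.informant_id: s.score for s in knowledge_scores(ds)}
    assert scores["P00"] == 6  # distinct species, not reports (10)
    assert scores["P01"] == 0  # informant without reports scores 0
    by_reports = {s.informant_id: s.score for s in knowledge_scores(ds, unit="reports")}
    assert by_reports["P00"] == 10


def test_knowledge_scores_match_bruteforce_on_random_data():
    rng = np.random.default_rng(11)
    for _ in range(25):
        ds = random_dataset(rng)
        scores = {s.informant_id: s.score for s in knowledge_scores(ds)}
        expected: dict[str, set] = {i.informant_id: set() for i in ds.informants}
        for rep in ds.use_reports:
            expected[rep.informant_id].add(rep.taxon)
        assert scores == {k: len(v) for k, v in expected.items()}


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _informants(groups):
    out = []
    for g, (label, n) in enumerate(groups):
        for i in range(n):
            out.append(
                InformantRecord(f"G{g}_{i:03d}", "male", label, "primary", "5-10", "family")
            )
    return out


def _scores(informants, values):
    return {inf.informant_id: v for inf, v in zip(informants, values)}


def test_identical_groups_give_t_zero():
    informants = _informants([("21-40", 3), ("41-60", 3)])
    scores = _scores(informants, [1, 2, 3, 3, 2, 1])
    comp = compare_groups(scores, informants, "age_group")
    assert comp.statistic_name == "t"
    assert comp.statistic == pytest.approx(0.0)


def test_swapping_group_labels_flips_t_and_keeps_permutation_p():
    rng = np.random.default_rng(3)
    informants = _informants([("21-40", 12), (">60", 8)])
    values = list(rng.normal(5, 1, 12)) + list(rng.normal(7, 1, 8))
    scores = _scores(informants, values)
    swapped = [
        InformantRecord(i.informant_id, i.gender, ">60" if i.age_group == "21-40" else "21-40",
                        i.education, i.experience_group, i.knowledge_source)
        for i in informants
    ]
    a = compare_groups(scores, informants, "age_group", method="permutation",
                       n_permutations=500, seed=9)
    b = compare_groups(scores, swapped, "age_group", method="permutation",
                       n_permutations=500, seed=9)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_value == b.p_value


def test_permutation_p_is_seed_reproducible_and_order_invariant():
    rng = np.random.default_rng(4)
    informants = _informants([("21-40", 10), ("41-60", 10)])
    values = list(rng.normal(0, 1, 20))
    scores = _scores(informants, values)
    p1 = compare_groups(scores, informants, "age_group", method="permutation",
                        n_permutations=400, seed=5).p_value
    p2 = compare_groups(scores, informants, "age_group", method="permutation",
                        n_permutations=400, seed=5).p_value
    shuffled = list(informants)
    np.random.default_rng(0).shuffle(shuffled)
    p3 = compare_groups(scores, shuffled, "age_group", method="permutation",
                        n_permutations=400, seed=5).p_value
    assert p1 == p2 == p3


def test_strong_shift_detected_by_permutation():
    rng = np.random.default_rng(12)
    informants = _informants([("21-40", 200), (">60", 200)])
    values = list(rng.normal(5, 1, 200)) + list(rng.normal(8, 1, 200))
    comp = compare_groups(_scores(informants, values), informants, "age_group",
                          method="permutation", n_permutations=10_000, seed=8)
    assert comp.p_value < 0.001


def test_three_groups_use_f_statistic():
    rng = np.random.default_rng(13)
    informants = _informants([("<20", 8), ("21-40", 8), (">60", 8)])
    values = list(rng.normal(0, 1, 24))
    comp = compare_groups(_scores(informants, values), informants, "age_group")
    assert comp.statistic_name == "F"
    assert 0 <= comp.p_value <= 1
    perm = compare_groups(_scores(informants, values), informants, "age_group",
                          method="permutation", n_permutations=300, seed=2)
    assert perm.statistic == pytest.approx(comp.statistic)


def test_single_group_stratum_is_degenerate():
    informants = _informants([("21-40", 5)])
    with pytest.raises(DegenerateStratificationError):
        compare_groups(_scores(informants, range(5)), informants, "age_group")
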