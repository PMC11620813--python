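"""Consensus index formulas, the index-table builder, and the fixture regression."""

from __future__ import annotations

import numpy as np
import pytest

from ethnoquant import (
    ConsistencyError,
    DegenerateCategoryError,
    EmptyInputError,
    UndefinedDenominatorError,
    build_index_table,
    display_fiv,
    display_icf,
    display_rfc,
    display_uv,
    fiv,
    icf,
    index_table_from_counts,
    ppv,
    rfc,
    uv,
)

from conftest import bruteforce_counts, make_dataset, random_dataset


# ---------------------------------------------------------------------------
# scalar formulas
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "FC, N, expected",
    [(0, 55, 0.000), (55, 55, 1.000), (36, 55, 0.655), (3, 55, 0.055), (29, 55, 0.527)],
)
def test_rfc_examples(FC, N, expected):
    assert display_rfc(rfc(FC, N)) == expected


@pytest.mark.parametrize(
    "U, N, expected",
    [(0, 55, 0.000), (37, 55, 0.673), (34, 55, 0.618), (4, 55, 0.073)],
)
def test_uv_examples(U, N, expected):
    assert display_uv(uv(U, N)) == expected


@pytest.mark.parametrize(
    "fc, N, expected",
    [(0, 55, 0), (55, 55, 100), (46, 55, 84), (3, 55, 6), (14, 55, 26), (25, 55, 46), (36, 55, 66)],
)
def test_fiv_examples(fc, N, expected):
    # The integer display follows the two-stage rounding of published
    # percentage tables (25.4545 -> 25.5 -> 26).
    assert display_fiv(fiv(fc, N)) == expected


def test_fiv_full_precision_value():
    assert fiv(46, 55) == pytest.approx(83.636363, abs=1e-5)


@pytest.mark.parametrize(
    "Nur, Nt, expected",
    [(361, 29, 0.922), (8, 3, 0.714), (87, 8, 0.919), (5, 5, 0.000), (2, 2, 0.000)],
)
def test_icf_examples(Nur, Nt, expected):
    assert display_icf(icf(Nur, Nt)) == expected


def test_denominator_and_consistency_errors():
    with pytest.raises(UndefinedDenominatorError):
        rfc(0, 0)
    with pytest.raises(UndefinedDenominatorError):
        uv(1, 0)
    with pytest.raises(ConsistencyError):
        rfc(6, 5)
    with pytest.raises(ConsistencyError):
        fiv(6, 5)
    with pytest.raises(ConsistencyError):
        icf(3, 4)
    with pytest.raises(DegenerateCategoryError):
        icf(1, 1)


def test_icf_bounds_exhaustive():
    """0 <= ICF <= 1 for every valid (Nur, Nt) with Nt <= Nur <= 60."""
    for nur in range(2, 61):
        for nt in range(1, nur + 1):
            value = icf(nur, nt)
            assert 0.0 <= value <= 1.0


# ---------------------------------------------------------------------------
# PPV modes
# ---------------------------------------------------------------------------

def test_ppv_single_leaf_species_both_modes():
    ds = make_dataset([(0, 0, "cough", "leaf")], 1, 1)
    for mode in ("species", "use_report"):
        table = ppv(ds, mode=mode)
        assert list(table["part"]) == ["leaf"]
        assert table["PPV"].iloc[0] == 100.0


def test_ppv_use_report_mode_sums_to_100():
    rng = np.random.default_rng(42)
    for _ in range(20):
        ds = random_dataset(rng)
        if not ds.use_reports:
            continue
        assert ppv(ds, mode="use_report")["PPV"].sum() == pytest.approx(100.0, abs=0.1)


def test_ppv_fixture_species_mode(urambo_dataset):
    table = ppv(urambo_dataset, mode="species")
    values = dict(zip(table["part"], table["PPV"].round(1)))
    assert values["bark"] == 21.4
    assert values["whole plant"] == 7.1
    assert values["leaf"] == 38.1
    assert values["rhizome"] == 2.4


def test_ppv_empty_dataset_errors():
    ds = make_dataset([], 0, 0)
    with pytest.raises(EmptyInputError):
        ppv(ds, mode="species")


# ---------------------------------------------------------------------------
# build_index_table
# ---------------------------------------------------------------------------

def test_minimal_dataset_indices():
    ds = make_dataset([(0, 0, "cough", "leaf")], 1, 1)
    table = build_index_table(ds)
    row = table.species.iloc[0]
    assert row["FC"] == 1 and row["U"] == 1
    assert row["RFC"] == 1.0 and row["UV"] == 1.0
    assert table.families["FIV"].iloc[0] == 100.0
    cough = table.categories.set_index("category").loc["cough"]
    assert bool(cough["degenerate"])  # Nur = 1: ICF undefined, flagged
    assert np.isnan(cough["ICF"])


def test_fc_counts_informants_and_u_counts_reports():
    # one informant citing one species for two ailments: FC 1, U 2 (UV > RFC)
    ds = make_dataset([(0, 0, "cough", "leaf"), (0, 0, "flu", "leaf")], 2, 1)
    row = build_index_table(ds).species.iloc[0]
    assert row["FC"] == 1 and row["U"] == 2
    assert row["UV"] > row["RFC"]


def test_adding_new_informant_increases_fc_and_uv():
    base = [(0, 0, "cough", "leaf")]
    ds1 = make_dataset(base, 3, 1)
    ds2 = make_dataset(base + [(1, 0, "cough", "leaf")], 3, 1)
    t1, t2 = build_index_table(ds1).species.iloc[0], build_index_table(ds2).species.iloc[0]
    assert t2["FC"] == t1["FC"] + 1
    assert t2["UV"] >= t1["UV"]
    f1 = build_index_table(ds1).families["FIV"].iloc[0]
    f2 = build_index_table(ds2).families["FIV"].iloc[0]
    assert f2 >= f1


def test_index_table_matches_bruteforce_on_random_datasets():
    rng = np.random.default_rng(20240902)
    for _ in range(100):
        ds = random_dataset(rng)
        table = build_index_table(ds)
        oracle = bruteforce_counts(ds)
        for row in table.species.to_dict("records"):
            assert row["FC"] == oracle["FC"].get(row["taxon"], 0)
            assert row["U"] == oracle["U"].get(row["taxon"], 0)
        for row in table.families.to_dict("records"):
            assert row["fc"] == oracle["fc"].get(row["family"], 0)
        for row in table.categories.to_dict("records"):
            assert row["Nur"] == oracle["Nur"].get(row["category"], 0)
            assert row["Nt"] == oracle["Nt"].get(row["category"], 0)


# ---------------------------------------------------------------------------
# fixture regression: printed values from inverted counts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def urambo_table(urambo):
    return index_table_from_counts(
        urambo.species_counts, urambo.family_counts, urambo.category_counts,
        n_informants=55, dataset=urambo.dataset,
    )


def test_fixture_species_indices_reproduce_printed_values(urambo, urambo_table):
    merged = urambo_table.species.merge(urambo.species_counts, on=["taxon", "family"])
    for row in merged.to_dict("records"):
        assert display_rfc(row["RFC"]) == row["rfc_printed"], row["taxon"]
        assert display_uv(row["UV"]) == row["uv_printed"], row["taxon"]


def test_fixture_family_indices_reproduce_printed_values(urambo, urambo_table):
    merged = urambo_table.families.merge(urambo.family_counts, on="family")
    for row in merged.to_dict("records"):
        assert display_fiv(row["FIV"]) == row["fiv_printed"], row["family"]


def test_fixture_icf_reproduces_printed_values(urambo, urambo_table):
    merged = urambo_table.categories.merge(urambo.category_counts, on="category")
    for row in merged.to_dict("records"):
        assert display_icf(row["ICF"]) == row["icf_printed"], row["category"]


def test_fixture_extremes(urambo_table):
    sp = urambo_table.species
    assert sp.loc[sp["RFC"].idxmax(), "taxon"] == "Zingiber officinale"
    assert display_rfc(sp["RFC"].max()) == 0.655
    assert display_rfc(sp["RFC"].min()) == 0.055
    assert sp.loc[sp["UV"].idxmax(), "taxon"] == "Entada abyssinica"
    assert display_uv(sp["UV"].max()) == 0.673
    fam = urambo_table.families
    assert fam.loc[fam["FIV"].idxmax(), "family"] == "Fabaceae"
    assert display_fiv(fam["FIV"].max()) == 84


def test_family_counts_inconsistent_with_species_counts_raise(urambo):
    bad = urambo.family_counts.copy()
    bad.loc[bad["family"] == "Fabaceae", "fc"] = 2  # below the best species' FC
    with pytest.raises(ConsistencyError):
        index_table_from_counts(urambo.species_counts, bad, urambo.category_counts, 55)
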