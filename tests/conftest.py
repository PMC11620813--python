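"""Shared fixtures: the packaged survey, tiny hand-built datasets, and a
brute-force index recount that serves as the independent oracle."""

from __future__ import annotations

import numpy as np
import pytest

from ethnoquant import (
    AilmentCategoryMap,
    InformantRecord,
    PlantRecord,
    SurveyDataset,
    UseReport,
    load_urambo,
)

FAMILIES = ("Fabaceae", "Myrtaceae", "Rubiaceae", "Lamiaceae", "Rutaceae", "Asteraceae")
CATEGORIES = ("cough", "flu", "asthma")
PARTS = ("leaf", "root", "bark")


@pytest.fixture(scope="session")
def urambo():
    return load_urambo()


@pytest.fixture(scope="session")
def urambo_dataset(urambo):
    return urambo.dataset


def make_plant(i: int, ailments=CATEGORIES) -> PlantRecord:
    return PlantRecord(
        taxon=f"Genus speciesa{chr(97 + i)}",
        family=FAMILIES[i % len(FAMILIES)],
        local_name=f"local{i}",
        origin="native" if i % 2 else "introduced",
        life_form=("tree", "herb", "shrub")[i % 3],
        parts_used=(PARTS[i % len(PARTS)],),
        source=("wild", "cultivated", "both")[i % 3],
        ailments=tuple(ailments),
        iucn_category="LC",
    )


def make_dataset(report_tuples, n_informants: int, n_species: int) -> SurveyDataset:
    """Dataset from raw (informant_idx, species_idx, category, part) tuples."""
    plants = [make_plant(i) for i in range(n_species)]
    informants = [
        InformantRecord(f"P{i:02d}", "male" if i % 3 else "female",
                        ("<20", "21-40", "41-60", ">60")[i % 4],
                        "primary", "5-10", "family")
        for i in range(n_informants)
    ]
    cmap = AilmentCategoryMap({c: c for c in CATEGORIES})
    reports = [
        UseReport(f"P{g:02d}", plants[s].taxon, cat, part, "decoction", "oral")
        for g, s, cat, part in report_tuples
    ]
    return SurveyDataset.from_records(reports, plants, informants, cmap)


def random_dataset(rng: np.random.Generator) -> SurveyDataset:
    """A random small survey (≤10 informants, ≤6 species) for oracle checks."""
    n_inf = int(rng.integers(1, 11))
    n_sp = int(rng.integers(1, 7))
    n_rows = int(rng.integers(0, 40))
    tuples = {
        (
            int(rng.integers(n_inf)),
            int(rng.integers(n_sp)),
            CATEGORIES[rng.integers(len(CATEGORIES))],
            PARTS[rng.integers(len(PARTS))],
        )
        for _ in range(n_rows)
    }
    return make_dataset(sorted(tuples), n_inf, n_sp)


def bruteforce_counts(dataset: SurveyDataset) -> dict:
    """Independent recount of FC, U, fc, Nur, Nt from raw tuples.

    Pure-python sets over the report tuples; shares no code with
    ``build_index_table``.
    """
    informants_by_taxon: dict[str, set] = {}
    reports_by_taxon: dict[str, int] = {}
    informants_by_family: dict[str, set] = {}
    reports_by_category: dict[str, int] = {}
    taxa_by_category: dict[str, set] = {}
    family_of = {p.taxon: p.family for p in dataset.plants}
    seen = set()
    for r in dataset.use_reports:
        key = (r.informant_id, r.taxon, r.ailment, r.part_used, r.preparation, r.administration)
        assert key not in seen, "duplicate tuple leaked into dataset"
        seen.add(key)
        informants_by_taxon.setdefault(r.taxon, set()).add(r.informant_id)
        reports_by_taxon[r.taxon] = reports_by_taxon.get(r.taxon, 0) + 1
        informants_by_family.setdefault(family_of[r.taxon], set()).add(r.informant_id)
        cat = dataset.category_map.map(r.ailment)
        reports_by_category[cat] = reports_by_category.get(cat, 0) + 1
        taxa_by_category.setdefault(cat, set()).add(r.taxon)
    return {
        "FC": {t: len(s) for t, s in informants_by_taxon.items()},
        "U": dict(reports_by_taxon),
        "fc": {f: len(s) for f, s in informants_by_family.items()},
        "Nur": dict(reports_by_category),
        "Nt": {c: len(s) for c, s in taxa_by_category.items()},
    }
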