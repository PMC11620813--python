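"""Seedable generator of synthetic ethnomedicinal survey datasets.

The generative model is deliberately the simplest structure consistent with
the consensus indices:

* informant *g* cites species *s* with probability min(1, m_g · p_s),
  independently across informants and species, where p_s is the species'
  citation probability and m_g ≥ 0 multiplies it according to the
  informant's demographic group (knowledge heterogeneity, e.g. older
  practitioners knowing more plants);
* a citing informant contributes one use report per ailment category *k*
  of the species with probability q_{s,k}; if every category draw fails,
  one report is forced for the species' first category, so each citation
  yields at least one report (U ≥ FC by construction);
* demographic groups are assigned with exact marginal counts (largest
  remainder) and a seeded shuffle, so group sizes are deterministic.

Randomness comes from one root seed: per-informant generators are derived
with ``SeedSequence(seed, spawn_key=(1, i))``, which makes the output
independent of generation order and byte-identical across runs.

``calibrate_from_indices`` inverts published index tables into generator
parameters: p_s = RFC_s, and per-category report probabilities chosen so
the expected number of reports per citing informant matches U_s / FC_s
(accounting for the forced minimum report).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .fixture import UramboFixture, load_urambo
from .survey import (
    AGE_GROUPS,
    EDUCATION_LEVELS,
    EXPERIENCE_GROUPS,
    GENDER_CODES,
    KNOWLEDGE_SOURCES,
    AilmentCategoryMap,
    InformantRecord,
    PlantRecord,
    SurveyDataset,
    UseReport,
)

#: Demographic margins of the Urambo survey (fractions of the 55 informants).
URAMBO_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "gender": {"male": 45 / 55, "female": 10 / 55},
    "age_group": {"<20": 3 / 55, "21-40": 26 / 55, "41-60": 19 / 55, ">60": 7 / 55},
    "education": {"illiterate": 7 / 55, "primary": 44 / 55, "secondary": 3 / 55, "tertiary": 1 / 55},
    "experience_group": {"<5": 10 / 55, "5-10": 22 / 55, "11-15": 11 / 55, ">15": 12 / 55},
    "knowledge_source": {"family": 37 / 55, "herbalist": 13 / 55, "divine": 5 / 55},
}

_ATTRIBUTE_VALUES = {
    "gender": GENDER_CODES,
    "age_group": AGE_GROUPS,
    "education": EDUCATION_LEVELS,
    "experience_group": EXPERIENCE_GROUPS,
    "knowledge_source": KNOWLEDGE_SOURCES,
}


@dataclass(frozen=True)
class SpeciesProfile:
    """Generator parameters and attributes for one species."""

    taxon: str
    family: str
    citation_prob: float
    category_probs: tuple[tuple[str, float], ...]  # (category, q), ordered
    local_name: str = ""
    origin: str = "native"
    life_form: str = "tree"
    parts: tuple[str, ...] = ("leaf",)
    source: str = "wild"
    iucn_category: str = "NoRecord"
    preparations: tuple[str, ...] = ("decoction",)
    administrations: tuple[str, ...] = ("oral",)

    def validate(self) -> None:
        if not 0.0 <= self.citation_prob <= 1.0:
            raise ConfigError(f"{self.taxon}: citation_prob {self.citation_prob} outside [0, 1]")
        if not self.category_probs:
            raise ConfigError(f"{self.taxon}: at least one ailment category required")
        for category, q in self.category_probs:
            if not 0.0 <= q <= 1.0:
                raise ConfigError(f"{self.taxon}/{category}: report probability {q} outside [0, 1]")
        if not self.parts or not self.preparations or not self.administrations:
            raise ConfigError(f"{self.taxon}: parts/preparations/administrations must be non-empty")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic survey."""

    n_informants: int
    species: tuple[SpeciesProfile, ...]
    seed: int
    demographics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in URAMBO_DEMOGRAPHICS.items()}
    )
    strata_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_informants <= 0:
            raise ConfigError("n_informants must be positive")
        if not self.species:
            raise ConfigError("at least one species profile required")
        for profile in self.species:
            profile.validate()
        for attribute, proportions in self.demographics.items():
            if attribute not in _ATTRIBUTE_VALUES:
                raise ConfigError(f"unknown demographic attribute {attribute!r}")
            for group, p in proportions.items():
                if group not in _ATTRIBUTE_VALUES[attribute]:
                    raise ConfigError(f"unknown group {group!r} for {attribute}")
                if p < 0:
                    raise ConfigError(f"negative proportion for {attribute}={group}")
            if abs(sum(proportions.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{attribute} proportions must sum to 1")
        for attribute, multipliers in self.strata_effects.items():
            if attribute not in self.demographics:
                raise ConfigError(f"strata effect on {attribute!r} without demographic proportions")
            for group, m in multipliers.items():
                if group not in self.demographics[attribute]:
                    raise ConfigError(f"strata effect for unknown group {group!r} of {attribute}")
                if m < 0:
                    raise ConfigError("knowledge multipliers must be non-negative")


def _exact_group_counts(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n informants to groups."""
    groups = list(proportions)
    raw = np.array([proportions[g] * n for g in groups])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        for idx in order[:remainder]:
            counts[idx] += 1
    return dict(zip(groups, (int(c) for c in counts)))


def generate_survey(config: GeneratorConfig) -> SurveyDataset:
    """Draw one synthetic survey dataset (deterministic for a fixed seed)."""
    config.validate()
    n = config.n_informants
    width = max(4, len(str(n)))
    ids = [f"I{i + 1:0{width}d}" for i in range(n)]

    # Demographic assignment: exact marginal counts, seeded shuffle per
    # attribute (spawn_key=(0, j) keeps streams independent of each other
    # and of the citation draws).
    assignments: dict[str, list[str]] = {}
    for j, (attribute, proportions) in enumerate(config.demographics.items()):
        counts = _exact_group_counts(proportions, n)
        values = [g for g, k in counts.items() for _ in range(k)]
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0, j)))
        assignments[attribute] = list(np.array(values, dtype=object)[rng.permutation(n)])

    informants = tuple(
        InformantRecord(
            informant_id=ids[i],
            gender=assignments.get("gender", ["male"] * n)[i],
            age_group=assignments.get("age_group", ["21-40"] * n)[i],
            education=assignments.get("education", ["primary"] * n)[i],
            experience_group=assignments.get("experience_group", ["5-10"] * n)[i],
            knowledge_source=assignments.get("knowledge_source", ["family"] * n)[i],
        )
        for i in range(n)
    )

    multipliers = np.ones(n)
    for attribute, effect in config.strata_effects.items():
        for i in range(n):
            multipliers[i] *= effect.get(assignments[attribute][i], 1.0)

    plants = tuple(
        PlantRecord(
            taxon=profile.taxon,
            family=profile.family,
            local_name=profile.local_name,
            origin=profile.origin,
            life_form=profile.life_form,
            parts_used=profile.parts,
            source=profile.source,
            ailments=tuple(category for category, _ in profile.category_probs),
            iucn_category=profile.iucn_category,
            preparation_codes=profile.preparations,
            administration_codes=profile.administrations,
        )
        for profile in config.species
    )
    categories_seen: list[str] = []
    for profile in config.species:
        for category, _ in profile.category_probs:
            if category not in categories_seen:
                categories_seen.append(category)
    category_map = AilmentCategoryMap({c: c for c in categories_seen})

    p = np.array([profile.citation_prob for profile in config.species])
    reports: list[UseReport] = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, i)))
        cite = rng.random(len(p)) < np.minimum(1.0, multipliers[i] * p)
        for s in np.flatnonzero(cite):
            profile = config.species[s]
            q = np.array([qk for _, qk in profile.category_probs])
            hits = np.flatnonzero(rng.random(len(q)) < q)
            if hits.size == 0:
                hits = np.array([0])  # forced minimum: one report per citation
            for k in hits:
                category = profile.category_probs[k][0]
                part = profile.parts[rng.integers(len(profile.parts))]
                preparation = profile.preparations[rng.integers(len(profile.preparations))]
                administration = profile.administrations[rng.integers(len(profile.administrations))]
                reports.append(
                    UseReport(
                        informant_id=ids[i],
                        taxon=profile.taxon,
                        ailment=category,
                        part_used=part,
                        preparation=preparation,
                        administration=administration,
                    )
                )
    return SurveyDataset.from_records(reports, plants, informants, category_map)


# ---------------------------------------------------------------------------
# Calibration from published index tables
# ---------------------------------------------------------------------------

def _solve_report_prob(r: float, k: int) -> float:
    """q such that E[reports per citing informant] = kq + (1−q)^k equals r.

    The expectation includes the forced minimum report, so it is 1 at q = 0
    and k at q = 1 and increases monotonically; r is clipped into [1, k].
    """
    if k == 1:
        return 1.0
    r = min(max(r, 1.0), float(k))
    if r >= k:
        return 1.0

    def f(q: float) -> float:
        return k * q + (1.0 - q) ** k - r

    return float(brentq(f, 0.0, 1.0, xtol=1e-12))


def calibrate_from_indices(
    index_rows: pd.DataFrame,
    n_informants: int,
    seed: int = 0,
    plants: Sequence[PlantRecord] = (),
    category_map: AilmentCategoryMap | None = None,
    demographics: Mapping[str, Mapping[str, float]] | None = None,
    strata_effects: Mapping[str, Mapping[str, float]] | None = None,
) -> GeneratorConfig:
    """Invert a per-species index table into a :class:`GeneratorConfig`.

    ``index_rows`` needs columns ``taxon`` and ``RFC`` (and optionally
    ``UV``); p_s is set to RFC_s (the implied citation count is
    FC_s = round(RFC_s × n), recorded in the returned profiles through
    p_s itself).  When ``UV`` is present, per-category report
    probabilities are solved so that the expected use reports per species
    approximate UV_s × n.  Plant records, when given, supply attributes
    and the species' ailment categories (via ``category_map``).
    """
    if n_informants <= 0:
        raise ConfigError("n_informants must be positive")
    plant_of = {p.taxon: p for p in plants}
    profiles = []
    for row in index_rows.to_dict("records"):
        taxon = row["taxon"]
        p_s = float(row["RFC"])
        if not 0.0 <= p_s <= 1.0:
            raise ConfigError(f"{taxon}: RFC {p_s} outside [0, 1]")
        plant = plant_of.get(taxon)
        if plant is not None and category_map is not None:
            categories = []
            for label in plant.ailments:
                category = category_map.map(label)
                if category not in categories:
                    categories.append(category)
        else:
            categories = [str(row.get("category", "unspecified"))]
        k = len(categories)
        fc_implied = round(p_s * n_informants)
        if "UV" in row and not pd.isna(row["UV"]) and fc_implied > 0:
            u_implied = round(float(row["UV"]) * n_informants)
            q = _solve_report_prob(u_implied / fc_implied, k)
        else:
            q = 1.0 if k == 1 else 0.0
        profiles.append(
            SpeciesProfile(
                taxon=taxon,
                family=plant.family if plant else str(row.get("family", "Unknownaceae")),
                citation_prob=p_s,
                category_probs=tuple((c, q) for c in categories),
                local_name=plant.local_name if plant else "",
                origin=plant.origin if plant else "native",
                life_form=plant.life_form if plant else "tree",
                parts=plant.parts_used if plant else ("leaf",),
                source=plant.source if plant else "wild",
                iucn_category=plant.iucn_category if plant else "NoRecord",
                preparations=(plant.preparation_codes or ("decoction",)) if plant else ("decoction",),
                administrations=(plant.administration_codes or ("oral",)) if plant else ("oral",),
            )
        )
    kwargs = {}
    if demographics is not None:
        kwargs["demographics"] = demographics
    if strata_effects is not None:
        kwargs["strata_effects"] = strata_effects
    config = GeneratorConfig(
        n_informants=n_informants, species=tuple(profiles), seed=seed, **kwargs
    )
    config.validate()
    return config


def urambo_config(
    seed: int,
    n_informants: int = 55,
    age_effects: bool = True,
    fixture: UramboFixture | None = None,
) -> GeneratorConfig:
    """Generator configuration calibrated to the packaged Urambo survey.

    Citation probabilities come from the published RFC column, report
    probabilities from UV, species attributes from the species table, and
    demographic margins from the informant profile.  With
    ``age_effects=True`` the age groups carry knowledge multipliers
    proportional to the published group means, normalised so the
    informant-weighted mean multiplier is exactly 1 (the expected RFC per
    species then remains p_s).
    """
    fx = fixture if fixture is not None else load_urambo()
    rows = fx.species_counts.rename(columns={"rfc_printed": "RFC", "uv_printed": "UV"})
    strata_effects: dict[str, dict[str, float]] = {}
    if age_effects:
        ages = fx.demographics[fx.demographics["attribute"] == "age_group"]
        weights = ages["n"].to_numpy(dtype=float)
        means = ages["mean_score"].to_numpy(dtype=float)
        overall = float((weights * means).sum() / weights.sum())
        strata_effects["age_group"] = {
            group: float(mean / overall) for group, mean in zip(ages["group"], means)
        }
    return calibrate_from_indices(
        rows,
        n_informants=n_informants,
        seed=seed,
        plants=fx.dataset.plants,
        category_map=fx.dataset.category_map,
        strata_effects=strata_effects,
    )
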