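"""Descriptive categorical profiles and demographic knowledge comparisons.

Plant attributes (life form, origin, source, IUCN category, part) are
profiled over the species list; remedy attributes (preparation,
administration) over the use reports, since one species can enter many
formulations.  Informant knowledge is summarised as a per-informant score
(distinct species cited, by default) and compared across demographic strata
with a Welch t statistic (two groups) or a one-way F statistic (more), with
p-values either closed-form or by label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    DegenerateStratificationError,
    EmptyInputError,
)
from .rounding import round_half_up
from .survey import InformantRecord, SurveyDataset

SPECIES_ATTRIBUTES = ("life_form", "origin", "source", "iucn_category", "part")
REPORT_ATTRIBUTES = ("preparation", "administration")
PROFILE_ATTRIBUTES = SPECIES_ATTRIBUTES + REPORT_ATTRIBUTES

STRATA = ("gender", "age_group", "education", "experience_group", "knowledge_source")


@dataclass(frozen=True)
class CategoricalProfile:
    """Counts and percentage shares of one categorical attribute."""

    attribute: str
    counts: tuple[tuple[str, int], ...]  # (category, count), ordered
    denominator: int

    @property
    def proportions(self) -> tuple[tuple[str, float], ...]:
        return tuple((k, v / self.denominator * 100.0) for k, v in self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "attribute": self.attribute,
                "category": [k for k, _ in self.counts],
                "count": [v for _, v in self.counts],
                "percent": [round_half_up(v / self.denominator * 100.0, 1) for _, v in self.counts],
            }
        )

    def __getitem__(self, category: str) -> int:
        for k, v in self.counts:
            if k == category:
                return v
        raise KeyError(category)


def categorical_profile(dataset: SurveyDataset, attribute: str) -> CategoricalProfile:
    """Profile one attribute with its documented denominator.

    Species attributes are counted over plant records (denominator: species
    total; the multi-valued ``part`` attribute may sum above 100%); remedy
    attributes over use reports.  Categories are ordered by descending
    count, ties alphabetical.
    """
    if attribute not in PROFILE_ATTRIBUTES:
        raise ValueError(
            f"unknown attribute {attribute!r}; expected one of {PROFILE_ATTRIBUTES}"
        )
    counts: dict[str, int] = {}
    if attribute in SPECIES_ATTRIBUTES:
        if not dataset.plants:
            raise EmptyInputError("profile needs at least one plant record")
        for plant in dataset.plants:
            if attribute == "part":
                for part in plant.parts_used:
                    counts[part] = counts.get(part, 0) + 1
            else:
                value = getattr(plant, attribute)
                counts[value] = counts.get(value, 0) + 1
        denominator = dataset.n_species
    else:
        if not dataset.use_reports:
            raise EmptyInputError(f"profile of {attribute!r} needs use reports")
        for rep in dataset.use_reports:
            value = getattr(rep, attribute)
            counts[value] = counts.get(value, 0) + 1
        denominator = len(dataset.use_reports)
    ordered = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return CategoricalProfile(attribute=attribute, counts=ordered, denominator=denominator)


def ailment_species_counts(dataset: SurveyDataset, source: str = "auto") -> dict[str, int]:
    """Distinct species per ailment category (all map categories included).

    ``source="reports"`` counts species observed in the use reports per
    category — the Nt column of the consensus table.  ``source="plants"``
    counts species whose recorded ailments fall in the category, which is
    what a published species table supports.  ``auto`` uses reports when any
    exist, else the plant records.
    """
    if source not in ("auto", "reports", "plants"):
        raise ValueError(f"unknown source {source!r}")
    if source == "auto":
        source = "reports" if dataset.use_reports else "plants"
    per_category: dict[str, set] = {c: set() for c in dataset.category_map.categories}
    if source == "reports":
        for rep in dataset.use_reports:
            per_category[dataset.category_map.map(rep.ailment)].add(rep.taxon)
    else:
        for plant in dataset.plants:
            for label in plant.ailments:
                per_category[dataset.category_map.map(label)].add(plant.taxon)
    return {c: len(s) for c, s in per_category.items()}


@dataclass(frozen=True)
class KnowledgeScore:
    """Per-informant knowledge: number of distinct species (or reports) cited."""

    informant_id: str
    score: int


def knowledge_scores(dataset: SurveyDataset, unit: str = "species") -> tuple[KnowledgeScore, ...]:
    """One score per informant (zero-report informants score 0).

    ``unit="species"`` counts distinct species the informant cited;
    ``unit="reports"`` counts the informant's use reports.
    """
    if unit not in ("species", "reports"):
        raise ValueError(f"unknown unit {unit!r}")
    per_informant: dict[str, set | int] = {}
    for rep in dataset.use_reports:
        if unit == "species":
            per_informant.setdefault(rep.informant_id, set()).add(rep.taxon)
        else:
            per_informant[rep.informant_id] = per_informant.get(rep.informant_id, 0) + 1
    out = []
    for informant in dataset.informants:
        value = per_informant.get(informant.informant_id, 0)
        out.append(KnowledgeScore(informant.informant_id, len(value) if isinstance(value, set) else value))
    return tuple(out)


@dataclass(frozen=True)
class GroupComparison:
    """Knowledge-score comparison across the groups of one stratum."""

    stratum: str
    group_stats: tuple[tuple[str, int, float, float], ...]  # (group, n, mean, sd)
    statistic: float
    statistic_name: str  # "t" (two groups, Welch) or "F" (one-way)
    p_value: float
    method: str  # "closed_form" | "permutation"
    n_permutations: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.group_stats, columns=["group", "n", "mean_score", "sd_score"]
        )


def _welch_t(groups: Sequence[np.ndarray]) -> float:
    g1, g2 = groups
    m1, m2 = g1.mean(), g2.mean()
    v1 = g1.var(ddof=1) if len(g1) > 1 else 0.0
    v2 = g2.var(ddof=1) if len(g2) > 1 else 0.0
    se = np.sqrt(v1 / len(g1) + v2 / len(g2))
    if se == 0.0:
        return 0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)
    return float((m1 - m2) / se)


def _anova_f(groups: Sequence[np.ndarray]) -> float:
    result = stats.f_oneway(*groups)
    return float(result.statistic)


def compare_groups(
    scores: Iterable[KnowledgeScore] | Mapping[str, int],
    informants: Iterable[InformantRecord],
    stratum: str,
    method: str = "closed_form",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> GroupComparison:
    """Compare knowledge scores across the groups of one demographic stratum.

    Two non-empty groups give a Welch (unequal-variance) t statistic —
    appropriate for the highly unbalanced group sizes typical of survey
    demographics — more give a one-way F.  ``method="closed_form"`` takes
    the two-sided p from the reference distribution;
    ``method="permutation"`` permutes group labels ``n_permutations`` times
    (seed required) and reports the add-one two-sided estimate
    (1 + #{|T*| ≥ |T|}) / (1 + B).
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    if isinstance(scores, Mapping):
        score_of = dict(scores)
    else:
        score_of = {s.informant_id: s.score for s in scores}
    groups: dict[str, list[float]] = {}
    for informant in informants:
        if informant.informant_id not in score_of:
            raise ConfigError(f"no knowledge score for informant {informant.informant_id!r}")
        groups.setdefault(getattr(informant, stratum), []).append(
            float(score_of[informant.informant_id])
        )
    group_names = sorted(groups)
    arrays = [np.asarray(groups[g]) for g in group_names]
    if len(arrays) < 2:
        raise DegenerateStratificationError(
            f"stratum {stratum!r} has {len(arrays)} non-empty group(s); need at least 2"
        )

    if len(arrays) == 2:
        statistic_name, stat_fn = "t", _welch_t
    else:
        statistic_name, stat_fn = "F", _anova_f
    observed = stat_fn(arrays)

    if method == "closed_form":
        if statistic_name == "t":
            p_value = float(stats.ttest_ind(arrays[0], arrays[1], equal_var=False).pvalue)
        else:
            p_value = float(stats.f_oneway(*arrays).pvalue)
        n_perm = None
    elif method == "permutation":
        if seed is None:
            raise ConfigError("permutation method requires a seed")
        if n_permutations < 1:
            raise ConfigError("n_permutations must be at least 1")
        p_value = _permutation_pvalue(arrays, stat_fn, observed, n_permutations, seed)
        n_perm = n_permutations
    else:
        raise ValueError(f"unknown method {method!r}; expected closed_form or permutation")

    group_stats = tuple(
        (g, len(arr), float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)
        for g, arr in zip(group_names, arrays)
    )
    return GroupComparison(
        stratum=stratum,
        group_stats=group_stats,
        statistic=observed,
        statistic_name=statistic_name,
        p_value=p_value,
        method=method,
        n_permutations=n_perm,
    )


def _permutation_pvalue(arrays, stat_fn, observed, n_permutations, seed) -> float:
    """Two-sided label-permutation p, vectorised for the two-group case.

    The pooled sample is sorted and group sizes are taken in descending
    order before drawing permutations, so the estimate depends only on the
    multiset of scores and the multiset of group sizes — swapping group
    labels or reordering informants cannot change it.
    """
    rng = np.random.default_rng(seed)
    pooled = np.sort(np.concatenate(arrays))
    sizes = sorted((len(a) for a in arrays), reverse=True)
    if len(arrays) == 2:
        n1 = sizes[0]
        n = len(pooled)
        batch = max(1, min(n_permutations, int(2e7) // max(n, 1)))
        exceed = 0
        done = 0
        while done < n_permutations:
            b = min(batch, n_permutations - done)
            keys = rng.random((b, n))
            order = np.argsort(keys, axis=1)
            perm = pooled[order]
            g1, g2 = perm[:, :n1], perm[:, n1:]
            v1 = g1.var(axis=1, ddof=1) if n1 > 1 else np.zeros(b)
            v2 = g2.var(axis=1, ddof=1) if n - n1 > 1 else np.zeros(b)
            se = np.sqrt(v1 / n1 + v2 / (n - n1))
            diff = g1.mean(axis=1) - g2.mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf))
            exceed += int(np.sum(np.abs(t) >= abs(observed) - 1e-12))
            done += b
        return (1 + exceed) / (1 + n_permutations)
    # k-group F: loop (group sizes differ, scipy stat per permutation)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for size in sizes:
            parts.append(perm[start : start + size])
            start += size
        if stat_fn(parts) >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)
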