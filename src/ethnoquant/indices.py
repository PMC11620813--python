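"""Consensus indices for ethnomedicinal survey data.

Let N be the number of informants interviewed.  For a species *s* cited by
FC_s distinct informants with U_s use reports in total, and a botanical
family cited by fc informants:

* RFC  = FC / N                 (relative frequency of citation, in [0, 1])
* UV   = U / N                  (use value; exceeds RFC when informants
                                 report several uses of the same plant)
* FIV  = fc / N × 100           (family importance value, percent)
* PPV  = RU_part / ΣRU × 100    (plant part value: the share of remedy
                                 formulations attributed to one plant part)
* ICF  = (Nur − Nt) / (Nur − 1) (informant consensus factor per ailment
                                 category with Nur use reports spread over
                                 Nt species; near 1 means many reports
                                 concentrated on few species)

``build_index_table`` counts FC, U, fc, Nur and Nt from raw use reports:
FC and fc count *distinct informants*, U and Nur count use reports, Nt
counts distinct species per category.  ``index_table_from_counts`` applies
the same formulas to pre-tabulated integer counts (as published survey
tables usually are).

PPV ships in two modes.  ``use_report`` mode implements the formula
literally: the denominator is the total number of use reports, so the
percentages sum to 100.  ``species`` mode divides the number of species
whose used parts include the part by the number of species; the sum may
exceed 100 because one species can contribute several parts.  Published
part-value percentages are often species fractions, so ``species`` is the
default for reproducing survey tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DegenerateCategoryError,
    EmptyInputError,
    UndefinedDenominatorError,
)
from .rounding import round_chain, round_half_up
from .survey import SurveyDataset

PPV_MODES = ("species", "use_report")


def _check_n(n) -> None:
    if not isinstance(n, Integral):
        raise ConsistencyError(f"N must be an integer, got {n!r}")
    if n == 0:
        raise UndefinedDenominatorError("N = 0: indices are undefined without informants")
    if n < 0:
        raise ConsistencyError(f"N must be positive, got {n}")


def _check_count(name: str, value) -> None:
    if not isinstance(value, Integral):
        raise ConsistencyError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise ConsistencyError(f"{name} must be non-negative, got {value}")


def rfc(FC: int, N: int) -> float:
    """Relative frequency of citation FC/N (0 ≤ FC ≤ N)."""
    _check_n(N)
    _check_count("FC", FC)
    if FC > N:
        raise ConsistencyError(f"FC = {FC} exceeds N = {N}")
    return FC / N


def fiv(fc: int, N: int) -> float:
    """Family importance value fc/N × 100 (0 ≤ fc ≤ N)."""
    _check_n(N)
    _check_count("fc", fc)
    if fc > N:
        raise ConsistencyError(f"fc = {fc} exceeds N = {N}")
    return fc / N * 100.0


def uv(U: int, N: int) -> float:
    """Use value U/N (U ≥ 0; may exceed 1 when informants report many uses)."""
    _check_n(N)
    _check_count("U", U)
    return U / N


def icf(Nur: int, Nt: int) -> float:
    """Informant consensus factor (Nur − Nt)/(Nur − 1) for Nur > 1.

    A category with a single use report (Nur = 1) has an undefined ICF and
    raises :class:`DegenerateCategoryError` rather than silently scoring 0.
    """
    _check_count("Nur", Nur)
    _check_count("Nt", Nt)
    if Nt < 1:
        raise ConsistencyError(f"Nt must be at least 1, got {Nt}")
    if Nt > Nur:
        raise ConsistencyError(f"Nt = {Nt} exceeds Nur = {Nur}")
    if Nur == 1:
        raise DegenerateCategoryError("ICF undefined for a category with a single use report (Nur = 1)")
    return (Nur - Nt) / (Nur - 1)


def jaccard_index(a: int, b: int, c: int) -> float:
    """Checklist similarity c/(a + b + c) × 100 (re-exported convenience).

    See :mod:`ethnoquant.similarity` for the checklist-level interface.
    """
    from .similarity import jaccard_index as _ji

    return _ji(a, b, c)


# ---------------------------------------------------------------------------
# Display rounding (the reporting boundary)
# ---------------------------------------------------------------------------

def display_rfc(value: float) -> float:
    return round_half_up(value, 3)


display_uv = display_rfc
display_icf = display_rfc


def display_fiv(value: float) -> int:
    """FIV as printed in survey tables: half-up to 1 decimal, then to integer.

    Spreadsheet-era source tables round the percentage to one decimal first
    and round the displayed value again to an integer, so fc/N×100 = 25.4545…
    prints as 26, not 25.  The chain is applied here so recomputed tables
    diff cleanly against transcriptions.
    """
    return int(round_chain(value, 1, 0))


def display_percent(value: float) -> float:
    return round_half_up(value, 1)


# ---------------------------------------------------------------------------
# Index table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexTable:
    """Per-species, per-family, per-part and per-category index tables.

    ``species``    columns taxon, family, FC, U, RFC, UV
    ``families``   columns family, fc, FIV
    ``parts``      columns part, RU, PPV, mode
    ``categories`` columns category, Nur, Nt, ICF, degenerate
                   (degenerate marks Nur ≤ 1, where ICF is undefined/NaN)
    """

    n_informants: int
    species: pd.DataFrame
    families: pd.DataFrame
    parts: pd.DataFrame
    categories: pd.DataFrame

    def rounded(self) -> "IndexTable":
        """Copy with index columns rounded to reporting precision."""
        sp = self.species.copy()
        sp["RFC"] = sp["RFC"].map(display_rfc)
        sp["UV"] = sp["UV"].map(display_uv)
        fam = self.families.copy()
        fam["FIV"] = fam["FIV"].map(display_fiv)
        pa = self.parts.copy()
        if len(pa):
            pa["PPV"] = pa["PPV"].map(display_percent)
        ca = self.categories.copy()
        ca["ICF"] = ca["ICF"].map(lambda v: v if pd.isna(v) else display_icf(v))
        return IndexTable(self.n_informants, sp, fam, pa, ca)

    def summary(self) -> str:
        """Plain-text digest of the headline numbers."""
        lines = [
            f"informants (N): {self.n_informants}",
            f"species: {len(self.species)}  families: {len(self.families)}",
        ]
        sp = self.species
        if len(sp) and sp["FC"].sum() > 0:
            top_rfc = sp.loc[sp["RFC"].idxmax()]
            top_uv = sp.loc[sp["UV"].idxmax()]
            lines.append(f"highest RFC: {top_rfc['taxon']} ({display_rfc(top_rfc['RFC']):.3f})")
            lines.append(f"highest UV: {top_uv['taxon']} ({display_uv(top_uv['UV']):.3f})")
        fam = self.families
        if len(fam) and fam["fc"].sum() > 0:
            top_fiv = fam.loc[fam["FIV"].idxmax()]
            lines.append(f"highest FIV: {top_fiv['family']} ({display_fiv(top_fiv['FIV'])})")
        ca = self.categories
        valid = ca[~ca["degenerate"]]
        if len(valid):
            top_icf = valid.loc[valid["ICF"].idxmax()]
            lines.append(f"highest ICF: {top_icf['category']} ({display_icf(top_icf['ICF']):.3f})")
        return "\n".join(lines)


def ppv(dataset: SurveyDataset, mode: str = "species") -> pd.DataFrame:
    """Plant part value per part code present in the dataset.

    ``use_report`` mode counts cited uses per part over all use reports (the
    percentages sum to 100); ``species`` mode counts species whose used parts
    include the part over the species total (the sum may exceed 100).
    """
    if mode not in PPV_MODES:
        raise ValueError(f"unknown PPV mode {mode!r}; expected one of {PPV_MODES}")
    if mode == "species":
        if not dataset.plants:
            raise EmptyInputError("PPV (species mode) needs at least one plant record")
        counts: dict[str, int] = {}
        for plant in dataset.plants:
            for part in plant.parts_used:
                counts[part] = counts.get(part, 0) + 1
        denominator = dataset.n_species
    else:
        if not dataset.use_reports:
            raise EmptyInputError("PPV (use_report mode) needs at least one use report")
        counts = {}
        for rep in dataset.use_reports:
            counts[rep.part_used] = counts.get(rep.part_used, 0) + 1
        denominator = len(dataset.use_reports)
    order = sorted(counts, key=lambda p: (-counts[p], p))
    return pd.DataFrame(
        {
            "part": order,
            "RU": [counts[p] for p in order],
            "PPV": [counts[p] / denominator * 100.0 for p in order],
            "mode": mode,
        }
    )


def build_index_table(dataset: SurveyDataset, ppv_mode: str = "species") -> IndexTable:
    """Count FC, U, fc, Nur, Nt from raw use reports and apply the indices.

    FC and fc count distinct informants (per species and per family), U and
    Nur count use reports, Nt counts distinct species per ailment category.
    Species and family rows cover every plant record, cited or not; category
    rows cover every category of the map.  Rows are deterministically
    ordered: species by (family, taxon), categories by (ICF desc, Nur, name).
    """
    n = dataset.n_informants
    reports = dataset.use_reports_frame(with_category=True)
    taxon_family = {p.taxon: p.family for p in dataset.plants}

    if len(reports):
        fc_by_taxon = reports.groupby("taxon")["informant_id"].nunique()
        u_by_taxon = reports.groupby("taxon").size()
        fam_series = reports["taxon"].map(taxon_family)
        fc_by_family = reports.groupby(fam_series)["informant_id"].nunique()
        nur = reports.groupby("category").size()
        nt = reports.groupby("category")["taxon"].nunique()
    else:
        fc_by_taxon = u_by_taxon = fc_by_family = nur = nt = pd.Series(dtype=int)

    species_rows = []
    for plant in sorted(dataset.plants, key=lambda p: (p.family, p.taxon)):
        FC = int(fc_by_taxon.get(plant.taxon, 0))
        U = int(u_by_taxon.get(plant.taxon, 0))
        species_rows.append(
            {
                "taxon": plant.taxon,
                "family": plant.family,
                "FC": FC,
                "U": U,
                "RFC": rfc(FC, n) if n else np.nan,
                "UV": uv(U, n) if n else np.nan,
            }
        )
    species = pd.DataFrame(
        species_rows, columns=["taxon", "family", "FC", "U", "RFC", "UV"]
    )

    family_rows = []
    for family in sorted({p.family for p in dataset.plants}):
        fc_count = int(fc_by_family.get(family, 0))
        family_rows.append(
            {"family": family, "fc": fc_count, "FIV": fiv(fc_count, n) if n else np.nan}
        )
    families = pd.DataFrame(family_rows, columns=["family", "fc", "FIV"])

    category_rows = []
    for category in dataset.category_map.categories:
        Nur = int(nur.get(category, 0))
        Nt = int(nt.get(category, 0))
        degenerate = Nur <= 1
        category_rows.append(
            {
                "category": category,
                "Nur": Nur,
                "Nt": Nt,
                "ICF": np.nan if degenerate else icf(Nur, Nt),
                "degenerate": degenerate,
            }
        )
    categories = pd.DataFrame(
        category_rows, columns=["category", "Nur", "Nt", "ICF", "degenerate"]
    )
    categories = categories.sort_values(
        by=["ICF", "Nur", "category"], ascending=[False, True, True], na_position="last"
    ).reset_index(drop=True)

    try:
        parts = ppv(dataset, mode=ppv_mode)
    except EmptyInputError:
        parts = pd.DataFrame(columns=["part", "RU", "PPV", "mode"])

    return IndexTable(n, species, families, parts, categories)


def index_table_from_counts(
    species_counts: pd.DataFrame,
    family_counts: pd.DataFrame,
    category_counts: pd.DataFrame,
    n_informants: int,
    dataset: SurveyDataset | None = None,
    ppv_mode: str = "species",
) -> IndexTable:
    """Apply the index formulas to pre-tabulated integer counts.

    ``species_counts`` needs columns taxon, family, FC, U; ``family_counts``
    needs family, fc; ``category_counts`` needs category, Nur, Nt.  When a
    ``dataset`` is given its plant records supply the part table.  Family
    counts are cross-checked against species counts: the informants citing a
    family can be no fewer than those citing its best-cited species and no
    more than the per-species sum.
    """
    _check_n(n_informants)
    n = n_informants
    species = species_counts.copy()
    species["FC"] = species["FC"].astype(int)
    species["U"] = species["U"].astype(int)
    species["RFC"] = [rfc(v, n) for v in species["FC"]]
    species["UV"] = [uv(v, n) for v in species["U"]]
    species = (
        species[["taxon", "family", "FC", "U", "RFC", "UV"]]
        .sort_values(["family", "taxon"])
        .reset_index(drop=True)
    )

    families = family_counts.copy()
    families["fc"] = families["fc"].astype(int)
    fc_stats = species.groupby("family")["FC"].agg(["max", "sum"])
    for _, row in families.iterrows():
        if row["family"] in fc_stats.index:
            lo = int(fc_stats.loc[row["family"], "max"])
            hi = int(fc_stats.loc[row["family"], "sum"])
            if not lo <= row["fc"] <= hi:
                raise ConsistencyError(
                    f"family {row['family']!r}: fc = {row['fc']} outside [max FC, sum FC] = [{lo}, {hi}]"
                )
    families["FIV"] = [fiv(v, n) for v in families["fc"]]
    families = families[["family", "fc", "FIV"]].sort_values("family").reset_index(drop=True)

    categories = category_counts.copy()
    categories["Nur"] = categories["Nur"].astype(int)
    categories["Nt"] = categories["Nt"].astype(int)
    categories["degenerate"] = categories["Nur"] <= 1
    categories["ICF"] = [
        np.nan if d else icf(int(nur_), int(nt_))
        for nur_, nt_, d in zip(categories["Nur"], categories["Nt"], categories["degenerate"])
    ]
    categories = (
        categories[["category", "Nur", "Nt", "ICF", "degenerate"]]
        .sort_values(by=["ICF", "Nur", "category"], ascending=[False, True, True], na_position="last")
        .reset_index(drop=True)
    )

    if dataset is not None:
        parts = ppv(dataset, mode=ppv_mode)
    else:
        parts = pd.DataFrame(columns=["part", "RU", "PPV", "mode"])
    return IndexTable(n, species, families, parts, categories)
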