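"""Packaged Urambo District survey fixture.

The fixture transcribes a published respiratory-ailment plant survey from
mid-western Tanzania: 42 medicinal plant species in 28 botanical families,
cited by 55 traditional health practitioners.  Raw per-informant use
reports were never published, so alongside the verbatim species-attribute
table the fixture carries *inverted integer counts* reconstructed from the
printed indices with N = 55:

    FC_s = round(RFC_s × 55)      (informants citing species s)
    U_s  = round(UV_s × 55)       (use reports for species s)
    fc_f = round(FIV_f × 55/100)  (informants citing family f)

together with the published per-category use-report counts (Nur, Nt), the
cross-study checklist totals, and the demographic margins.  The inversion
is exact in the sense that re-applying the index formulas to the integer
counts reproduces every printed index value at its printed precision; the
few source-table cells that are internally inconsistent are listed under
``metadata["discrepancies"]`` rather than silently repaired.

The informant table contains 55 synthetic rows whose *marginal* counts per
demographic attribute equal the published profile exactly; the joint
assignment is arbitrary (the paper publishes only margins).  The use-report
table is header-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .survey import SurveyDataset, load_survey

FIXTURE_NAME = "urambo"


def fixture_dir(name: str = FIXTURE_NAME) -> Path:
    """Filesystem path of a packaged fixture directory."""
    return Path(str(resources.files("ethnoquant") / "fixtures" / name))


@dataclass(frozen=True)
class UramboFixture:
    """The packaged survey: validated dataset plus published count tables."""

    dataset: SurveyDataset
    species_counts: pd.DataFrame   # taxon, family, FC, U, rfc_printed, uv_printed
    family_counts: pd.DataFrame    # family, fc, fiv_printed
    category_counts: pd.DataFrame  # category, Nur, Nt, icf_printed
    checklists: pd.DataFrame       # study_label, region, other_total, present_total, common, ji_printed
    demographics: pd.DataFrame     # attribute, group, n, percent, mean_score, sd_score, p_value
    metadata: dict

    @property
    def n_informants(self) -> int:
        return self.dataset.n_informants


def load_urambo() -> UramboFixture:
    """Load the packaged Urambo fixture."""
    root = fixture_dir()
    dataset = load_survey(
        root / "use_reports.csv",
        root / "plants.csv",
        root / "informants.csv",
        root / "ailment_map.csv",
    )
    numeric = {"FC": int, "U": int, "fc": int, "Nur": int, "Nt": int,
               "other_total": int, "present_total": int, "common": int, "n": int}

    def read(name: str) -> pd.DataFrame:
        frame = pd.read_csv(root / name, dtype=str, na_filter=False, encoding="utf-8")
        for col in frame.columns:
            if col in numeric:
                frame[col] = frame[col].astype(int)
            elif col.endswith("_printed") or col in ("percent", "mean_score", "sd_score", "p_value"):
                frame[col] = pd.to_numeric(frame[col], errors="coerce")
        return frame

    metadata = json.loads((root / "metadata.json").read_text(encoding="utf-8"))
    return UramboFixture(
        dataset=dataset,
        species_counts=read("species_counts.csv"),
        family_counts=read("family_counts.csv"),
        category_counts=read("category_counts.csv"),
        checklists=read("checklists.csv"),
        demographics=read("demographics.csv"),
        metadata=metadata,
    )
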