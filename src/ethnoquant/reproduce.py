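"""One-command reproduction of the published Urambo survey tables.

``run_reproduce`` rebuilds, from the packaged fixture, the per-species
RFC/UV table, the per-family FIV table, the plant-part values, the
per-category ICF table, the cross-study checklist comparison, and the
descriptive profiles; writes them as CSVs plus a plain-text summary; and
regression-checks every recomputed index cell against the printed value it
should reproduce.  Cells the source tables themselves get wrong (listed in
the fixture metadata under ``discrepancies``) are excluded from the check
and reported in the summary instead.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import EthnoquantError, RegressionMismatchError
from .fixture import UramboFixture, fixture_dir, load_urambo
from .indices import (
    display_fiv,
    display_icf,
    display_rfc,
    display_uv,
    index_table_from_counts,
)
from .profiles import PROFILE_ATTRIBUTES, REPORT_ATTRIBUTES, ailment_species_counts, categorical_profile
from .similarity import display_ji, jaccard_index


@dataclass(frozen=True)
class ReproduceReport:
    """Outcome of a reproduction run."""

    out_dir: Path
    files: tuple[str, ...]
    checks_passed: int
    mismatches: tuple[str, ...]
    summary: str


def _checks(fx: UramboFixture, ppv_mode: str):
    """Yield (label, recomputed, expected) triples plus the output tables."""
    n = fx.n_informants
    table = index_table_from_counts(
        fx.species_counts,
        fx.family_counts,
        fx.category_counts,
        n_informants=n,
        dataset=fx.dataset,
        ppv_mode=ppv_mode,
    )
    printed_rfc = dict(zip(fx.species_counts["taxon"], fx.species_counts["rfc_printed"]))
    printed_uv = dict(zip(fx.species_counts["taxon"], fx.species_counts["uv_printed"]))
    printed_fiv = dict(zip(fx.family_counts["family"], fx.family_counts["fiv_printed"]))
    printed_icf = dict(zip(fx.category_counts["category"], fx.category_counts["icf_printed"]))

    checks = []
    for row in table.species.to_dict("records"):
        checks.append((f"RFC[{row['taxon']}]", display_rfc(row["RFC"]), float(printed_rfc[row["taxon"]])))
        checks.append((f"UV[{row['taxon']}]", display_uv(row["UV"]), float(printed_uv[row["taxon"]])))
    for row in table.families.to_dict("records"):
        checks.append((f"FIV[{row['family']}]", float(display_fiv(row["FIV"])), float(printed_fiv[row["family"]])))
    for row in table.categories.to_dict("records"):
        checks.append((f"ICF[{row['category']}]", display_icf(row["ICF"]), float(printed_icf[row["category"]])))

    comparisons = fx.checklists.copy()
    comparisons["JI"] = [
        display_ji(jaccard_index(int(a), int(b), int(c)))
        for a, b, c in zip(comparisons["present_total"], comparisons["other_total"], comparisons["common"])
    ]
    for row in comparisons.to_dict("records"):
        checks.append((f"JI[{row['study_label']}]", row["JI"], float(row["ji_printed"])))

    nt_by_category = ailment_species_counts(fx.dataset, source="plants")
    for row in fx.category_counts.to_dict("records"):
        checks.append((f"Nt[{row['category']}]", float(nt_by_category[row["category"]]), float(row["Nt"])))

    return table, comparisons, checks


def run_reproduce(out_dir, ppv_mode: str = "species", seed: int | None = None, strict: bool = True) -> ReproduceReport:
    """Rebuild the published tables from the fixture and regression-check them.

    All output is rendered in memory first; files are only written once the
    whole bundle exists, so a failing run leaves no partial output.  With
    ``strict=True`` any unexplained mismatch raises
    :class:`RegressionMismatchError` after the report files are written.
    """
    fx = load_urambo()
    table, comparisons, checks = _checks(fx, ppv_mode)
    known = set(fx.metadata.get("excluded_regression_cells", []))
    mismatches = [
        f"{label}: recomputed {got} != printed {want}"
        for label, got, want in checks
        if label not in known and abs(got - want) > 1e-9
    ]
    n_passed = sum(1 for label, *_ in checks if label not in known) - len(mismatches)

    rounded = table.rounded()
    digests = []
    for path in sorted(fixture_dir().glob("*.csv")):
        digests.append(f"{path.name} sha256={hashlib.sha256(path.read_bytes()).hexdigest()[:16]}")

    profile_frames = []
    for attribute in PROFILE_ATTRIBUTES:
        if attribute in REPORT_ATTRIBUTES and not fx.dataset.use_reports:
            continue  # fixture ships no raw reports; remedy profiles need them
        profile_frames.append(categorical_profile(fx.dataset, attribute).to_frame())
    profiles = pd.concat(profile_frames, ignore_index=True)

    comparisons_out = comparisons[
        ["study_label", "region", "other_total", "present_total", "common", "JI"]
    ]

    summary_lines = [
        f"ethnoquant {__version__} — Urambo survey reproduction",
        f"seed: {seed if seed is not None else 'n/a (deterministic run)'}",
        "fixture digests:",
        *(f"  {d}" for d in digests),
        "",
        table.summary(),
        "",
        f"regression checks passed: {n_passed}",
        f"known source-table discrepancies excluded: {len(known)}",
        *(f"  {cell}: {note}" for cell, note in fx.metadata.get("discrepancies", {}).items()),
    ]
    if mismatches:
        summary_lines.append("MISMATCHES:")
        summary_lines.extend(f"  {m}" for m in mismatches)
    summary = "\n".join(summary_lines) + "\n"

    # Render everything before touching the filesystem.
    rendered: dict[str, str] = {}

    def render(name: str, frame: pd.DataFrame) -> None:
        buf = io.StringIO()
        frame.to_csv(buf, index=False, lineterminator="\n")
        rendered[name] = buf.getvalue()

    render("species_indices.csv", rounded.species)
    render("family_indices.csv", rounded.families)
    render("part_values.csv", rounded.parts)
    render("category_icf.csv", rounded.categories)
    render("comparisons.csv", comparisons_out)
    render("profiles.csv", profiles)
    rendered["summary.txt"] = summary

    out_dir = Path(out_dir)
    written: list[str] = []
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, text in rendered.items():
            (out_dir / name).write_text(text, encoding="utf-8")
            written.append(name)
    except OSError as exc:
        for name in written:
            try:
                (out_dir / name).unlink()
            except OSError:
                pass
        raise EthnoquantError(f"cannot write report bundle to {out_dir}: {exc}") from exc

    report = ReproduceReport(
        out_dir=out_dir,
        files=tuple(rendered),
        checks_passed=n_passed,
        mismatches=tuple(mismatches),
        summary=summary,
    )
    if strict and mismatches:
        raise RegressionMismatchError(mismatches)
    return report
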