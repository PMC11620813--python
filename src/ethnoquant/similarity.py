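"""Cross-study species-checklist comparison.

The similarity statistic used for ethnomedicinal checklist comparisons is

    JI = c / (a + b + c) × 100

where *a* and *b* are the two studies' species totals (each already
including the shared species) and *c* is the number of species common to
both.  Note the denominator: this is *not* the classical Jaccard
coefficient c/(a + b − c); with full overlap (a = b = c) the statistic
tops out at 33.3, not 100.  The classical variant is available through
``variant="classical"`` for users who want the set-theoretic coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral
from typing import Iterable

import pandas as pd

from .errors import (
    ConsistencyError,
    IncompleteChecklistError,
    UndefinedDenominatorError,
)
from .rounding import round_half_up
from .survey import canonicalize_taxon

JI_VARIANTS = ("printed", "classical")


def jaccard_index(a: int, b: int, c: int, variant: str = "printed") -> float:
    """Checklist similarity from the two totals and the shared-species count.

    ``printed`` variant: c/(a + b + c) × 100 (the convention of published
    ethnomedicinal comparison tables); ``classical``: c/(a + b − c) × 100.
    """
    for name, value in (("a", a), ("b", b), ("c", c)):
        if not isinstance(value, Integral):
            raise ConsistencyError(f"{name} must be an integer, got {value!r}")
        if value < 0:
            raise ConsistencyError(f"{name} must be non-negative, got {value}")
    if c > min(a, b):
        raise ConsistencyError(f"c = {c} exceeds min(a, b) = {min(a, b)}")
    if variant not in JI_VARIANTS:
        raise ValueError(f"unknown JI variant {variant!r}; expected one of {JI_VARIANTS}")
    denominator = a + b + c if variant == "printed" else a + b - c
    if denominator == 0:
        raise UndefinedDenominatorError("a + b + c = 0: Jaccard index undefined")
    return c / denominator * 100.0


def display_ji(value: float) -> float:
    """JI at reporting precision (1 decimal, half-up)."""
    return round_half_up(value, 1)


@dataclass(frozen=True)
class Checklist:
    """One study's species checklist.

    Either the full set of canonical binomials (``taxa``) or, when only the
    headline numbers are published, the declared species total and
    (optionally) the declared number of species shared with the reference
    study.
    """

    study_label: str
    region: str = ""
    taxa: frozenset[str] | None = None
    declared_total: int | None = None
    declared_common: int | None = None

    def __post_init__(self):
        if self.taxa is not None and self.declared_total is not None:
            raise ConsistencyError(
                f"checklist {self.study_label!r}: give taxa or declared_total, not both"
            )
        if self.taxa is None and self.declared_total is None:
            raise IncompleteChecklistError(
                f"checklist {self.study_label!r} has neither a taxa set nor a declared total"
            )
        if self.declared_total is not None and self.declared_total <= 0:
            raise ConsistencyError(f"checklist {self.study_label!r}: declared_total must be positive")
        if self.declared_common is not None:
            if self.declared_common < 0:
                raise ConsistencyError("declared_common must be non-negative")
            if self.declared_total is not None and self.declared_common > self.declared_total:
                raise ConsistencyError(
                    f"checklist {self.study_label!r}: declared_common exceeds declared_total"
                )

    @classmethod
    def from_names(cls, study_label: str, names: Iterable[str], region: str = "") -> "Checklist":
        """Build a checklist from raw scientific names (canonicalized here)."""
        return cls(study_label=study_label, region=region,
                   taxa=frozenset(canonicalize_taxon(n) for n in names))

    @property
    def total(self) -> int:
        return len(self.taxa) if self.taxa is not None else int(self.declared_total)


@dataclass(frozen=True)
class ChecklistComparison:
    """The (a, b, c, JI) record for one pair of studies."""

    study_label: str
    region: str
    a: int
    b: int
    c: int
    JI: float

    @property
    def common(self) -> int:
        return self.c


def compare_checklists(
    present: Checklist, other: Checklist, variant: str = "printed"
) -> ChecklistComparison:
    """Compare the present study's checklist with another study's.

    The shared-species count c comes from exact canonical-binomial set
    intersection when both taxa sets exist, otherwise from the other study's
    declared count.  The statistic is symmetric in the roles of a and b.
    """
    a = present.total
    b = other.total
    if present.taxa is not None and other.taxa is not None:
        c = len(present.taxa & other.taxa)
    elif other.declared_common is not None:
        c = int(other.declared_common)
    elif present.declared_common is not None:
        c = int(present.declared_common)
    else:
        raise IncompleteChecklistError(
            f"checklist pair ({present.study_label!r}, {other.study_label!r}): "
            "no taxa sets and no declared common count"
        )
    return ChecklistComparison(
        study_label=other.study_label,
        region=other.region,
        a=a,
        b=b,
        c=c,
        JI=jaccard_index(a, b, c, variant=variant),
    )


def compare_many(
    present: Checklist, others: Iterable[Checklist], variant: str = "printed"
) -> pd.DataFrame:
    """Tabulate comparisons against several studies (one row per study)."""
    rows = []
    for other in others:
        comp = compare_checklists(present, other, variant=variant)
        rows.append(
            {
                "study_label": comp.study_label,
                "region": comp.region,
                "other_total": comp.b,
                "present_total": comp.a,
                "common": comp.c,
                "JI": comp.JI,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["study_label", "region", "other_total", "present_total", "common", "JI"]
    )
    return frame.sort_values("JI", ascending=False, kind="stable").reset_index(drop=True)
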