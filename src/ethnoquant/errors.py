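"""Exception hierarchy.

Every error carries a short machine-parsable ``code`` so the command-line
layer can emit single-line diagnostics (``ERROR <code>: <message>``).
"""

from __future__ import annotations


class EthnoquantError(Exception):
    """Base class for all package errors."""

    code = "ETQ000"


class SchemaError(EthnoquantError):
    """An input table is missing a required column or has a malformed cell."""

    code = "ETQ001"


class ReferentialError(EthnoquantError):
    """A use report references an unknown taxon or informant."""

    code = "ETQ002"


class MappingError(EthnoquantError):
    """One or more ailment labels cannot be resolved to a category."""

    code = "ETQ003"

    def __init__(self, labels, message: str | None = None):
        self.labels = tuple(labels)
        if message is None:
            message = "unmapped ailment label(s): " + ", ".join(repr(x) for x in self.labels)
        super().__init__(message)


class TaxonParseError(EthnoquantError, ValueError):
    """A scientific name cannot be reduced to a Genus-epithet binomial."""

    code = "ETQ004"


class ConsistencyError(EthnoquantError, ValueError):
    """Counts violate a structural constraint (e.g. FC > N or c > min(a, b))."""

    code = "ETQ005"


class UndefinedDenominatorError(EthnoquantError, ZeroDivisionError):
    """An index denominator is zero (N = 0, or a + b + c = 0)."""

    code = "ETQ006"


class DegenerateCategoryError(EthnoquantError):
    """ICF is undefined for a category with a single use report (Nur = 1)."""

    code = "ETQ007"


class EmptyInputError(EthnoquantError):
    """An operation that needs data received an empty dataset."""

    code = "ETQ008"


class ConfigError(EthnoquantError, ValueError):
    """A generator or pipeline configuration is invalid."""

    code = "ETQ009"


class IncompleteChecklistError(EthnoquantError):
    """A checklist has neither a taxa list nor declared totals."""

    code = "ETQ010"


class DegenerateStratificationError(EthnoquantError):
    """A demographic stratum has fewer than two non-empty groups."""

    code = "ETQ011"


class RegressionMismatchError(EthnoquantError):
    """Reproduction run disagrees with the packaged expected values."""

    code = "ETQ012"

    def __init__(self, mismatches, message: str | None = None):
        self.mismatches = tuple(mismatches)
        if message is None:
            message = "regression mismatch in %d cell(s): %s" % (
                len(self.mismatches),
                "; ".join(str(m) for m in self.mismatches),
            )
        super().__init__(message)
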