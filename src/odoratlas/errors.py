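"""Exception hierarchy for curation and analysis failures.

Every failure mode that the curation rules treat as a hard error (an
unmapped odorant name, a molar concentration without a molecular weight,
an EAG study without a reference odorant, ...) raises a dedicated
exception rather than passing data through silently: a silently
mis-standardized record is worse than a rejected one.
"""


class OdorAtlasError(Exception):
    """Base class for all package-specific errors."""


class UnmappedOdorantError(OdorAtlasError, KeyError):
    """An odorant name has no entry in the synonym table."""


class UndefinedIndexError(OdorAtlasError, ValueError):
    """Preference index requested with zero animals in both arms."""


class RangeError(OdorAtlasError, ValueError):
    """A numeric input lies outside its documented domain."""


class MissingMolecularWeightError(OdorAtlasError, ValueError):
    """A molar concentration cannot be converted without the compound MW."""


class MissingReferenceError(OdorAtlasError, ValueError):
    """An unnormalized EAG study has no record for the reference odorant."""


class DegenerateFitError(OdorAtlasError, ValueError):
    """Tuning-curve fit requested on degenerate data (e.g. constant x)."""


class FitFailureError(OdorAtlasError, RuntimeError):
    """Nonlinear least squares failed to converge; carries diagnostics."""


class EmptySelectionError(OdorAtlasError, ValueError):
    """A filter or join produced no usable rows."""


class SkippedComparison(OdorAtlasError):
    """A comparison was skipped because it fails the minimum-data rule.

    Carries ``reason`` and the observed count so callers can log the skip.
    """

    def __init__(self, reason: str, n: int | None = None):
        super().__init__(reason)
        self.reason = reason
        self.n = n


class ConfigError(OdorAtlasError, ValueError):
    """An invalid configuration (split fractions, simulator parameters)."""
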