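"""Exception hierarchy.

All package-specific failures derive from :class:`KaspError` so callers can
catch one base class at pipeline boundaries.
"""


class KaspError(Exception):
    """Base class for all kaspfp errors."""


class ConfigurationError(KaspError, ValueError):
    """A configuration field is outside its stated domain."""


class VcfParseError(KaspError):
    """The input could not be parsed as VCF (e.g. missing #CHROM header)."""


class VcfFormatError(KaspError):
    """The VCF is structurally valid but lacks a required field (e.g. GT)."""


class ReferenceLookupError(KaspError, KeyError):
    """A chromosome/position was not found in the reference sequence."""


class ReferenceMismatchError(KaspError):
    """The reference base at a SNP position does not match the variant REF."""


class InsufficientContextError(KaspError):
    """Flanking context is too short to place the requested primer windows."""


class GatingError(KaspError):
    """A fluorescence plate cannot be gated (no NTC wells)."""


class UnsupportedMarkerError(KaspError):
    """A marker violates the biallelic-SNP assumption."""


class UndefinedStatisticError(KaspError):
    """A statistic has no defined value (e.g. zero called samples)."""


class DegenerateInputError(KaspError):
    """Input carries no usable variation (e.g. all-constant genotype matrix)."""


class ArityError(KaspError, ValueError):
    """Wrong number of inputs (e.g. fewer than two replicate call sets)."""
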