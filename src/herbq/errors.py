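"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`HerbQError`
so callers (and the CLI) can catch one base class. Subclasses distinguish the
failure modes that callers are expected to handle differently.
"""


class HerbQError(Exception):
    """Base class for all errors raised by herbq."""


class InputError(HerbQError, ValueError):
    """Malformed or out-of-domain user input (bad values, bad file content)."""


class AlignmentError(InputError):
    """Alignment-level invariant violated (ragged lengths, duplicate ids...)."""


class ConfigError(InputError):
    """Invalid grouping / panel / run configuration."""


class CoverageError(InputError):
    """A species required by the grouping is absent from the alignment."""


class PanelError(HerbQError):
    """A site panel cannot be assembled (e.g. no group-diagnostic site)."""


class DegenerateMixtureError(InputError):
    """Mixture has no amplifying mass, so allele frequencies are undefined."""


class DegenerateFitError(InputError):
    """Standard-curve fit is impossible (no variance in the proportions)."""


class UnquantifiableSampleError(HerbQError):
    """External-standard frequency is zero: total mass cannot be deduced."""


class MissingDataError(HerbQError):
    """No measurements available for a site that a computation requires."""


class NoValidStandardError(HerbQError):
    """Every candidate external standard is already present in the sample."""


class UnresolvedCompositionError(HerbQError):
    """Adulteration detected but no species-diagnostic site identifies it."""
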