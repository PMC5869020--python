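"""Exception hierarchy shared across the package."""


class ArborKitError(Exception):
    """Base class for all arborkit errors."""


class SWCFormatError(ArborKitError):
    """Malformed SWC content: bad columns, duplicate ids, unparsable fields."""


class SkeletonTopologyError(ArborKitError):
    """Parent references that do not form a single rooted tree."""


class UndefinedValueError(ArborKitError):
    """A quantity that is mathematically undefined for the given input
    (e.g. bendiness of a branch whose endpoints coincide)."""


class NoPeakError(ArborKitError):
    """An intensity profile with no interior maximum above background."""


class TruncatedPeakError(ArborKitError):
    """A peak whose half-maximum level is never crossed on one side."""
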