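"""Exception hierarchy shared across the pipeline."""


class TailoseqError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(TailoseqError):
    """Invalid simulation or run configuration."""


class FormatError(TailoseqError):
    """Malformed input file; message names the offending line or cell."""


class PairingError(TailoseqError):
    """A treated sample has no (or an ambiguous) Time0 partner."""


class EmptyAssayError(TailoseqError):
    """No strain passed the usability filter in a sample."""


class AnchorNotFoundError(TailoseqError):
    """A flanking anchor gene is absent from the genome."""


class AmbiguousAnchorError(TailoseqError):
    """A flanking anchor gene occurs more than once."""


class SplitLocusError(TailoseqError):
    """The two flanking anchors lie on different contigs."""
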