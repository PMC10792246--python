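"""Exception hierarchy shared across the toolkit."""


class EffluxKitError(Exception):
    """Base class for all toolkit errors."""


class DegenerateWellError(EffluxKitError):
    """Both medium and lysate signals are zero."""


class PairingError(EffluxKitError):
    """A required companion well (mock, mock-no-acceptor, WT) is missing."""


class ExperimentInvalidError(EffluxKitError):
    """WT specific efflux is non-positive; the experiment cannot normalize."""


class InsufficientReplicatesError(EffluxKitError):
    """Fewer replicates than the operation requires."""


class CalibrationError(EffluxKitError):
    """Threshold derivation lacks eligible calibration or control variants."""


class HgvsParseError(EffluxKitError):
    """Unsupported or malformed protein-level HGVS notation."""


class MsaMappingError(EffluxKitError):
    """Residue position cannot be mapped onto the alignment."""


class SimBoundsError(EffluxKitError):
    """Simulation parameters imply an impossible efflux fraction."""


class UndefinedCorrelationError(EffluxKitError):
    """Pearson correlation is undefined (constant channel)."""


class BlotMatchError(EffluxKitError):
    """Lanes compared across different blots/experiments."""
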