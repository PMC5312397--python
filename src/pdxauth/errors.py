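"""Exception hierarchy for pdxauth."""


class PDXAuthError(Exception):
    """Base class for all pdxauth errors."""


class PanelMismatchError(PDXAuthError):
    """A profile does not cover the assay panel it is compared or registered against."""


class DuplicateReferenceError(PDXAuthError):
    """Two registry entries share the same reference_id."""


class InsufficientEvidenceError(PDXAuthError):
    """Too little signal-level data to reach a decision (e.g. traces missing for >25% of loci)."""


class InputFormatError(PDXAuthError):
    """A structurally invalid input file (empty, duplicated rows, missing header...)."""
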