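"""Exception types shared across the package."""


class VocscreenError(Exception):
    """Base class for all vocscreen errors."""


class ParseError(VocscreenError):
    """A delimited-text or structure file could not be parsed."""


class ValidationError(VocscreenError):
    """Parsed data violates a domain invariant."""


class DegenerateVarianceError(VocscreenError):
    """All groups have zero within-group variance; Tukey HSD is undefined.

    Jitter the pose scores or skip the significance test for this panel.
    """
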