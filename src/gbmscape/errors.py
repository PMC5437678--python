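"""Exception hierarchy shared by all gbmscape modules."""


class GbmscapeError(Exception):
    """Base class for all errors raised by gbmscape."""


class FormatError(GbmscapeError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(GbmscapeError, ValueError):
    """Parsed values violate a domain invariant (counts, bounds, sets)."""


class ChromosomeMismatchError(ValidationError):
    """Two inputs use disjoint chromosome name sets."""

    def __init__(self, only_a, only_b, label_a="first input", label_b="second input"):
        self.only_a = sorted(only_a)
        self.only_b = sorted(only_b)
        super().__init__(
            f"chromosome names do not match: {label_a} only has "
            f"{self.only_a or '[]'}, {label_b} only has {self.only_b or '[]'}; "
            "no aliasing is applied, fix the input names"
        )
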