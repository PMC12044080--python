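"""Exception types shared across the pipeline."""


class HeartQTLError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(HeartQTLError, ValueError):
    """A simulation or analysis specification violates its invariants."""


class ConsistencyError(HeartQTLError, ValueError):
    """Inputs that must agree (markers vs counts, blocks vs paths) do not."""


class DegenerateInputError(HeartQTLError, ValueError):
    """Input is structurally valid but carries no usable information."""


class ParseError(HeartQTLError, ValueError):
    """An on-disk artifact violates its dialect; message carries the location."""
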