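"""Exception and warning hierarchy shared across the toolkit."""


class MethylightError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(MethylightError, ValueError):
    """A sequence contains a character outside the strict {A, C, G, T} alphabet."""

    def __init__(self, char: str, position: int, context: str = "sequence"):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid character {char!r} at position {position} in {context}: "
            "only A/C/G/T are accepted (ambiguity codes are rejected)"
        )


class OligoParseError(MethylightError, ValueError):
    """Annotated oligo text contains a non-base character after stripping decorations."""


class DesignError(MethylightError, ValueError):
    """An assay cannot be placed on a template (missing, multiple, or inverted primer hits)."""


class CloneScoringError(MethylightError, ValueError):
    """A clone cannot be scored against its reference (e.g. length mismatch)."""


class QuantificationError(MethylightError, ValueError):
    """A Ct table cannot be turned into relative copy numbers."""


class ControlFailureError(QuantificationError):
    """A run-level PCR control failed (contaminated negative or dead positive control)."""


class DiagnosticsError(MethylightError, ValueError):
    """Invalid input to ROC/contingency computations."""


class FixtureError(MethylightError, ValueError):
    """Infeasible synthetic-fixture specification."""


class MethylightWarning(UserWarning):
    """Base class for toolkit warnings."""


class BisulfiteWarning(MethylightWarning):
    """Ambiguous conversion context (e.g. a terminal cytosine with unknown CpG status)."""


class DesignWarning(MethylightWarning):
    """Suspicious but non-fatal assay design feature."""
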