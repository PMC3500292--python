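"""Exception hierarchy.

Distinct classes exist so the command line can map failure modes to
distinct exit codes (usage=2, parse=3, resolution=4).
"""


class BrassError(Exception):
    """Base class for all package errors."""


class ParseError(BrassError):
    """Malformed or empty input stream (PDB, PQR, OpenDX, CSV)."""


class UnsupportedFormatError(ParseError):
    """Input is syntactically valid but uses an unsupported variant."""


class MotifResolutionError(BrassError):
    """A motif specification could not be matched against a structure."""


class MissingAtomError(BrassError):
    """A residue lacks every atom in its functional-atom preference list."""


class OutOfGridError(BrassError):
    """A point falls outside the potential grid; extrapolation is refused."""


class SingularityError(BrassError):
    """Evaluation point coincides (within 0.1 A) with a source charge."""


class FixtureError(BrassError):
    """Inconsistent synthetic-fixture specification."""
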