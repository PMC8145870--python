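"""Exception hierarchy.

``JointScreenError`` is the base for everything the package raises on bad
input or an inconsistent design; the CLI maps it to exit status 1 (user
error) and any other exception to 2 (internal error).
"""


class JointScreenError(Exception):
    """Base class for all package errors."""


class SequenceError(JointScreenError):
    """Malformed nucleotide sequence (non-ACGT characters, empty input)."""


class DesignError(JointScreenError):
    """Cloning design violates an invariant (site counts, overhangs, probes)."""


class UncloneableGeneError(DesignError):
    """No built-in enzyme pair can clone this gene."""


class ProbeCollisionError(DesignError):
    """A junction probe is ambiguous (shared between genes or present in the
    empty vector) or the insert is too short to supply a specific flank."""


class EmptySampleError(JointScreenError):
    """A count table with zero joint-reads cannot be converted to percentages."""


class ConfigError(JointScreenError):
    """Invalid run or simulation configuration."""


class FastqFormatError(JointScreenError):
    """Truncated or malformed FASTQ input."""


class FastaFormatError(JointScreenError):
    """Malformed FASTA input."""
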