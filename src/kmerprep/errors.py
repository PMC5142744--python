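"""Exception hierarchy shared by all kmerprep modules.

Every error raised on user input derives from :class:`KmerprepError`, so
callers (and the command-line layer) can distinguish data problems from
programming bugs with a single except clause.
"""


class KmerprepError(Exception):
    """Base class for all errors raised on bad input or configuration."""


class InvalidAlphabetError(KmerprepError):
    """A sequence or k-mer contains a character outside the DNA alphabet."""


class KmerLengthError(KmerprepError):
    """A k-mer string does not match the length demanded by its KmerSpec."""


class EmptySequenceError(KmerprepError):
    """An operation that needs at least one valid k-mer received none."""


class ConfigurationError(KmerprepError):
    """Parameters are inconsistent with each other or with a data structure."""


class SketchFileError(KmerprepError):
    """A sketch/graph file on disk is corrupt, truncated, or mismatched."""


class SeedNotFoundError(KmerprepError):
    """A graph traversal was seeded with a k-mer that is not present."""


class ParseError(KmerprepError):
    """A FASTA/FASTQ stream is malformed; the message names the record."""
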