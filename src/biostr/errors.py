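"""Exception hierarchy for the bio-string library.

Every error raised by this package derives from :class:`BiostrError`, so
callers (and the CLI) can distinguish domain errors from programming errors.
"""


class BiostrError(Exception):
    """Base class for all bio-string domain errors."""


class AlphabetError(BiostrError, ValueError):
    """A residue outside the molecule's alphabet; names the character and its 1-based position."""

    def __init__(self, char: str, position: int, molecule: str):
        self.char = char
        self.position = position
        self.molecule = molecule
        super().__init__(
            f"illegal {molecule} residue {char!r} at position {position}"
        )


class FrameError(BiostrError, ValueError):
    """Reading frame outside {1, 2, 3}."""


class CodeTableError(BiostrError, ValueError):
    """Malformed genetic-code table (wrong codon count, duplicates, bad letters)."""


class TreeError(BiostrError, ValueError):
    """Taxonomy node set is not a tree (cycle, multiple roots, unreachable nodes)."""


class UnknownTaxonError(BiostrError, KeyError):
    """Queried taxonomy id is not present in the loaded taxonomy."""


class UnknownProteinError(BiostrError, KeyError):
    """Queried protein id is not present in the loaded proteins."""


class UnknownQueryError(BiostrError, KeyError):
    """Named query is not registered with the store."""


class SchemaExistsError(BiostrError, RuntimeError):
    """Target already contains the schema and overwrite was not requested."""


class ParseError(BiostrError, ValueError):
    """Malformed input file; carries the offending line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SpecError(BiostrError, ValueError):
    """Inconsistent synthetic-data specification."""


class IntegrityError(BiostrError, RuntimeError):
    """Referential-integrity violation during a strict load."""


class UsageError(BiostrError, ValueError):
    """Bad command-line usage (maps to exit code 1)."""
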