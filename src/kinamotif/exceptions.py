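"""Exception hierarchy for kinamotif.

All errors raised by the package derive from :class:`KinamotifError` so
callers (and the CLI) can catch package failures with one clause.
"""


class KinamotifError(Exception):
    """Base class for all kinamotif errors."""


class InvalidSequenceError(KinamotifError):
    """A protein sequence contains characters outside the 20 canonical codes."""

    def __init__(self, accession: str, bad_chars: set[str]):
        self.accession = accession
        self.bad_chars = sorted(bad_chars)
        super().__init__(
            f"sequence {accession!r} contains non-canonical characters: "
            f"{', '.join(self.bad_chars)}"
        )


class InvalidPeptideError(KinamotifError):
    """A centered 13-mer violates its invariants (length, center, J layout)."""


class CenterResidueError(InvalidPeptideError):
    """The residue at the phosphoacceptor position is not S, T or Y."""

    def __init__(self, residue: str, context: str = ""):
        self.residue = residue
        msg = f"center residue {residue!r} is not one of S, T, Y"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class SiteTableError(KinamotifError):
    """Malformed phosphosite table: missing columns or bad field values."""


class ProfileStoreError(KinamotifError):
    """Malformed or incompatible serialized profile store."""


class TooFewPeptidesError(KinamotifError):
    """A kinase has fewer peptides than the configured minimum."""

    def __init__(self, kinase: str, n: int, min_n: int):
        self.kinase = kinase
        self.n = n
        self.min_n = min_n
        super().__init__(
            f"kinase {kinase!r} has {n} peptides; minimum required is {min_n}"
        )


class NoEligibleKinasesError(KinamotifError):
    """Class restriction removed every profile from a ranking request."""
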