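"""Exception hierarchy shared across the package."""


class MocloSimError(Exception):
    """Base class for all package-specific errors."""


class SequenceError(MocloSimError):
    """Invalid DNA sequence, topology, or feature coordinates."""


class GenBankParseError(MocloSimError):
    """A GenBank file could not be read; the message names the path."""


class DatabaseError(MocloSimError):
    """Problem loading the input-plasmid database (duplicates, bad files)."""

    def __init__(self, message: str, loaded: dict | None = None):
        super().__init__(message)
        # molecules that did parse, so callers can report what *is* loadable
        self.loaded = loaded or {}


class DigestionError(MocloSimError):
    """Base for digestion problems."""


class NoSitesError(DigestionError):
    """The enzyme has no recognition site on the molecule (uncut circle)."""


class SingleCutError(DigestionError):
    """Exactly one cut on a circular molecule: a nicked circle, not a digest."""


class CutCollisionError(DigestionError):
    """Two cuts whose overhang regions partially overlap (malformed plasmid)."""


class NoReleasablePartError(DigestionError):
    """No recognition-free fragment: the plasmid releases nothing usable."""


class AmbiguousInsertError(DigestionError):
    """More than one recognition-free fragment; the insert is ambiguous."""


class ReactionError(MocloSimError):
    """A one-pot reaction failed; carries the offending plasmid id."""

    def __init__(self, message: str, plasmid_id: str | None = None):
        super().__init__(message)
        self.plasmid_id = plasmid_id


class GrammarError(MocloSimError):
    """Structurally invalid grammar or template request on one."""


class CampaignError(MocloSimError):
    """Campaign file or mapping problem; message cites row/column/token."""


class ResolutionError(CampaignError):
    """A part name could not be resolved to a plasmid in the database."""

    def __init__(self, message: str, token: str | None = None, column: int | None = None):
        super().__init__(message)
        self.token = token
        self.column = column


class VerificationError(MocloSimError):
    """PCR / restriction-digest simulation problem."""


class NoAmpliconError(VerificationError):
    """A primer has no binding site on the template; names the primer."""

    def __init__(self, message: str, primer_name: str | None = None):
        super().__init__(message)
        self.primer_name = primer_name


class UnknownEnzymeError(VerificationError):
    """Enzyme name not in the built-in or user tables."""


class QuantitationError(MocloSimError):
    """Dilution arithmetic problem (missing stock, infeasible volumes)."""
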