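"""Exception hierarchy.

Every error raised on bad user input derives from :class:`PanfamError`, so
callers (and the CLI) can catch one type. Programming errors still surface as
ordinary Python exceptions.
"""


class PanfamError(Exception):
    """Base class for all panfam input/usage errors."""


class MembershipFormatError(PanfamError):
    """Membership table is malformed (missing column, bad coordinate, ...)."""


class NameGrammarError(PanfamError):
    """A member name does not match any production of the naming grammar."""


class NameFormatError(PanfamError):
    """A name cannot be rendered in the requested style."""


class UnknownMemberError(NameGrammarError):
    """Core index in a name falls outside the profile's 1..K range."""


class DegenerateInputError(PanfamError):
    """Empty or otherwise degenerate sequence input."""


class UnassignableError(PanfamError):
    """Members carry neither a clade label nor a sequence to assign one from."""


class EmptyProfileError(PanfamError):
    """No clade reaches the presence threshold."""


class UnresolvedLocusError(PanfamError):
    """The modal chromosome of a core clade is tied and cannot be resolved."""


class ProfileMismatchError(PanfamError):
    """A member's clade label does not exist in the profile."""


class EmptySummaryError(PanfamError):
    """A summary was requested for an empty assignment set."""


class InvalidCodonError(PanfamError):
    """Codon is a stop, contains ambiguous bases, or is not 3 nt long."""


class FrameError(PanfamError):
    """Coding sequence length is not a multiple of 3 or the pair disagrees."""


class ConfigError(PanfamError):
    """Simulator configuration is inconsistent."""
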