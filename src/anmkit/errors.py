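"""Exception hierarchy for anmkit.

All errors derive from :class:`AnmError` so callers (notably the CLI) can map
failure classes to exit codes without string matching.
"""


class AnmError(Exception):
    """Base class for all anmkit errors."""


class PDBParseError(AnmError, ValueError):
    """A PDB record could not be parsed (message names the offending line)."""


class EmptyStructureError(PDBParseError):
    """Input contained no ATOM/HETATM record."""


class ConfigError(AnmError, ValueError):
    """Invalid scheme/range-table configuration."""


class DegenerateNetworkError(AnmError, ValueError):
    """Fewer than two nodes, coincident nodes, or no contacts at all."""


class DisconnectedNetworkError(AnmError, ValueError):
    """The spring network splits into more than one rigid component."""

    def __init__(self, message: str, n_components: int = 0):
        super().__init__(message)
        self.n_components = n_components


class DimensionError(AnmError, ValueError):
    """Array shapes incompatible with the node count."""
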