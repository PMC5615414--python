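"""Exception hierarchy.

Exit-code mapping in the CLI distinguishes configuration, parse/structure,
and statistical errors, so each family gets its own base class.
"""


class MirlitnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirlitnetError, ValueError):
    """Invalid configuration value (probability out of range, bad threshold, ...)."""


class LexiconError(MirlitnetError, ValueError):
    """Malformed or inconsistent lexicon (duplicate ids, alias collisions)."""


class ParseError(MirlitnetError, ValueError):
    """Malformed input file (XGMML/TSV/OBO); carries line or element context."""


class StructureError(MirlitnetError, ValueError):
    """Structurally invalid object (cyclic ontology, non-bipartite network)."""


class StatisticsError(MirlitnetError, ValueError):
    """Undefined statistical input (empty table, empty query set)."""


class GenerationError(MirlitnetError, RuntimeError):
    """Synthetic generator could not realize the requested ground truth."""


class PipelineError(MirlitnetError, RuntimeError):
    """A pipeline stage failed; names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
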