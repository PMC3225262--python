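"""Exception hierarchy for the GA framework."""


class PepgaError(Exception):
    """Base class for framework-specific failures."""


class DegenerateSelectionError(PepgaError):
    """Raised when every selection weight collapses to zero and no
    fitness-proportional draw is possible."""


class InfeasiblePopulationError(PepgaError):
    """Raised when pairwise-distinct peptides cannot be maintained, e.g. the
    sequence space is smaller than the population or the purge replacement
    loop exceeds its safety cap."""


class ExternalScorerError(PepgaError):
    """Raised when an external scoring command fails or returns output that
    cannot be matched one-to-one with the input peptides."""
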