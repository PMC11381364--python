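"""Exception hierarchy for the uindel pipeline."""


class UindelError(Exception):
    """Base class for all uindel-specific errors."""


class InvalidAlphabet(UindelError):
    """A sequence contains characters outside {A, C, G, T, U}."""


class BackboneMismatch(UindelError):
    """Pre-edited and fully edited sequences differ in their non-U backbone."""


class DegenerateTemplate(UindelError):
    """Pre-edited and fully edited sequences are identical at every editing site."""


class IndexOutOfRange(UindelError):
    """An editing-site index lies outside 1..n_es."""


class NotStandard(UindelError):
    """Operation requires a standard read (non-U sequence equal to the backbone)."""


class EmptyInput(UindelError):
    """A read population contained no reads."""


class EmptyPopulation(UindelError):
    """A sample has no standard reads to normalize."""


class TooFewControls(UindelError):
    """Fewer than two control samples were supplied."""


class TooFewSamples(UindelError):
    """Not enough samples per condition for a two-sample comparison."""


class InvalidSets(UindelError):
    """An editing-site set contains sites outside the testable universe."""


class InconsistentConfig(UindelError):
    """Simulation configuration is internally inconsistent."""


class ConfigError(UindelError):
    """Pipeline run configuration is invalid or incomplete."""
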