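"""Exception hierarchy shared across the package."""


class VTCombineError(Exception):
    """Base class for all package-specific errors."""


class ParseError(VTCombineError):
    """A file could not be parsed (names the offending line where possible)."""


class ValidationError(VTCombineError):
    """Parsed data violates an invariant (e.g. genotype count outside {0,1,2})."""


class DegeneratePhenotypeError(VTCombineError):
    """Phenotype is constant; no case/control contrast can be tested."""


class DegenerateGeneWarning(UserWarning):
    """A gene admits no non-degenerate threshold configuration (reported p = NA)."""
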