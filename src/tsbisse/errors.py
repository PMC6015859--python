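"""Exception hierarchy for tsbisse."""


class TsbisseError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(TsbisseError, ValueError):
    """Malformed newick input."""


class TreeValidationError(TsbisseError, ValueError):
    """A tree violates a structural invariant (polytomy, missing lengths, ...)."""


class UltrametricityError(TreeValidationError):
    """Tip ages deviate from zero beyond tolerance."""


class TraitError(TsbisseError, ValueError):
    """Trait table inconsistent with the companion tree or with itself."""


class LikelihoodError(TsbisseError, ValueError):
    """Non-finite or otherwise invalid likelihood evaluation."""


class ConvergenceError(TsbisseError, RuntimeError):
    """Optimizer or sampler failed to converge."""


class SimulationError(TsbisseError, RuntimeError):
    """Simulation rejection budget exhausted or infeasible conditioning."""
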