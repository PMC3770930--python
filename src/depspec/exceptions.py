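"""Exception types shared across the package."""


class NoCrossoverError(ValueError):
    """A crossover frequency was required but the spectrum has none."""


class ConvergenceError(RuntimeError):
    """An iterative procedure failed to converge within its budget."""


class InsufficientDataError(ValueError):
    """Too few samples to perform the requested estimate."""


class MissingControlError(InsufficientDataError):
    """No rate-ratio samples found near the control frequency."""


class CurvatureError(RuntimeError):
    """Newton step rejected: non-positive curvature of the objective."""


class SchemaError(ValueError):
    """A tabular input file violates the expected schema."""
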