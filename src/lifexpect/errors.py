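"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Input data violate a schema or domain constraint."""


class NonEstimableError(RuntimeError):
    """Stratum survival is not materially worse than the matched referents,
    so extrapolated life expectancy is undefined under the method's
    assumption; reported as a refusal, not a crash."""


class InsufficientFollowupError(RuntimeError):
    """Too few valid observed months to anchor the spline fit window."""
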