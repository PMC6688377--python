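"""Exception types used across the package."""


class ConfigurationError(ValueError):
    """A scenario/fee configuration is malformed or violates an invariant."""


class ScenarioError(RuntimeError):
    """A scenario failed mid-grid; carries whatever rows completed before it.

    Attributes
    ----------
    partial : pandas.DataFrame | None
        Summary rows for the scenarios that finished before the failure.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial
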