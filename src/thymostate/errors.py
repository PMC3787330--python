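"""Exception types shared across the package."""


class ModelError(Exception):
    """A model document is structurally or semantically invalid."""


class CompileError(ModelError):
    """A valid model cannot be compiled to the requested backend."""


class SimulationError(Exception):
    """A simulation failed at run time."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message if t is None else f"{message} (at t={t})")
        self.t = t
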