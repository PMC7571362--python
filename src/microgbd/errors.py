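"""Exception hierarchy for the microgbd pipeline."""


class MicroGBDError(Exception):
    """Base class for all microgbd errors."""


class ValidationError(MicroGBDError):
    """Input values violate a documented contract (range, schema, shape)."""


class StructuralError(MicroGBDError):
    """A registry graph is malformed (cycle, dangling parent, duplicate id)."""


class FitError(MicroGBDError):
    """A statistical fit could not be carried out (singular design, etc.)."""


class DegenerateDataError(MicroGBDError):
    """Data carry no usable signal (e.g. zero deaths everywhere)."""


class CrosswalkError(MicroGBDError):
    """No crosswalk coefficient exists for a (cause, category) pair."""


class PlanningError(MicroGBDError):
    """A holdout plan cannot be constructed from the observations given."""


class PredictionError(MicroGBDError):
    """A prediction was requested outside the fitted covariate table."""


class SplitError(MicroGBDError):
    """A cause-nature split was requested for a cell absent from the matrix."""


class CapabilityError(MicroGBDError):
    """An output was requested that the cause can never produce
    (e.g. deaths for a non-fatal-only cause)."""


class PipelineError(MicroGBDError):
    """A pipeline stage failed; carries the stage name for resumability."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
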