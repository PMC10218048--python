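"""Exception hierarchy shared across the package."""


class MirfluidError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirfluidError):
    """A file does not conform to the expected tabular schema."""


class ValidationError(MirfluidError):
    """Input data violates a documented invariant (range, label, shape)."""


class EstimationError(MirfluidError):
    """Too little data to estimate distribution parameters."""


class ImputationError(MirfluidError):
    """A profile cannot be imputed (nothing observed to condition on)."""


class GenerationError(MirfluidError):
    """Rejection sampling exhausted its proposal budget."""


class TrainingError(MirfluidError):
    """A classifier cannot be fit (class missing or below minimum count)."""


class FoldError(MirfluidError):
    """A cross-validation training fold lost an entire class."""


class ModelLoadError(MirfluidError):
    """A serialized model file is corrupted or incomplete."""
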