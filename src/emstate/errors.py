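"""Exception hierarchy shared across the pipeline."""


class EmstateError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EmstateError):
    """Input violates a precondition (empty matrix, negative Cq, ...)."""


class InsufficientReplicatesError(EmstateError):
    """A group has too few samples for a two-sample test."""


class ShortageError(EmstateError):
    """Fewer qualifying genes than requested for a signature."""


class NoOverlapError(EmstateError):
    """A signature shares no genes with a patient's expression profile."""


class DegenerateCohortError(EmstateError):
    """No usable cutoff / no events: survival statistics undefined."""


class MissingBackgroundError(EmstateError):
    """No NTC wells and no global background fallback configured."""


class MissingAssayError(EmstateError):
    """A requested panel gene has no assay on the plate."""


class InvalidSpecError(EmstateError):
    """Synthetic-data specification is inconsistent."""
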