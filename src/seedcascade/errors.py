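"""Exception hierarchy shared across the package."""


class SeedCascadeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SeedCascadeError, ValueError):
    """A caller supplied an argument outside the documented contract."""


class PlacementError(SeedCascadeError, RuntimeError):
    """Seed footprints could not be placed without overlap."""


class DegenerateCalibrationError(SeedCascadeError, ValueError):
    """White and dark references coincide at some voxel."""


class EmptySelectionError(SeedCascadeError, ValueError):
    """A band-trimming or selection step produced an empty result."""


class InvalidTrainingSetError(SeedCascadeError, ValueError):
    """The training set cannot support the requested fit (e.g. one class)."""


class DivergenceError(SeedCascadeError, RuntimeError):
    """An optimization produced a non-finite loss."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class MissingModelError(SeedCascadeError, KeyError):
    """A cascade prediction routed to a variety with no registered model."""

    def __init__(self, variety: str):
        super().__init__(f"no GM-status model registered for variety {variety!r}")
        self.variety = variety
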