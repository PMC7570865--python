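"""Exception types shared across the package."""


class FirevalError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(FirevalError):
    """Two rasters that must share a grid geometry do not."""


class GeometryError(FirevalError):
    """Invalid polygon geometry (e.g. self-intersecting rings)."""


class EmptyReferenceError(FirevalError):
    """An operation is undefined because the reference map has no burned area."""


class InfeasiblePackingError(FirevalError):
    """The synthetic generator could not place the requested fires."""

    def __init__(self, requested_px: int, achieved_px: int, message: str = ""):
        self.requested_px = requested_px
        self.achieved_px = achieved_px
        msg = message or (
            f"could not place requested burned area: achieved {achieved_px} "
            f"of {requested_px} pixels"
        )
        super().__init__(msg)


class DegenerateInputError(FirevalError):
    """A statistic is undefined for this input (zero variance, too few points...)."""
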