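"""Value-to-color mapping with a balanced-zero guarantee.

The balanced scale makes the display range symmetric about zero,
[-M, M] with M = max|value|, and uses an odd number of bins so a true
middle bin straddles 0 — the gradient's middle color (white by default)
then represents exactly zero.  Colors are linearly interpolated in sRGB
between the low, middle and high palette anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import LinearSegmentedColormap, to_hex, to_rgb

from .io import EmptyInputError, InputError

logger = logging.getLogger("heatclust")

DEFAULT_PALETTE = ("#0000FF", "#FFFFFF", "#FF0000")  # blue -> white -> red
DEFAULT_BINS = 255
MISSING_INDEX = -1
MISSING_COLOR = "#B3B3B3"


@dataclass
class ColorScale:
    """k color bins over [v_min, v_max] with k+1 strictly increasing breakpoints."""

    breakpoints: np.ndarray  # (k+1,)
    colors: list[str]        # k hex colors
    balanced: bool
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if self.breakpoints.ndim != 1 or self.breakpoints.size != len(self.colors) + 1:
            raise InputError("need k+1 breakpoints for k colors")
        if not (np.diff(self.breakpoints) > 0).all():
            raise InputError("breakpoints must be strictly increasing")
        if self.balanced and not np.isclose(self.v_min, -self.v_max):
            raise InputError("balanced scale requires v_min == -v_max")

    @property
    def k(self) -> int:
        return len(self.colors)

    @property
    def middle_index(self) -> int:
        return (self.k - 1) // 2


def _interpolate_palette(palette, k: int) -> list[str]:
    anchors = [to_rgb(c) for c in palette]
    cmap = LinearSegmentedColormap.from_list("heatclust", anchors, N=k)
    return [to_hex(cmap(i / max(k - 1, 1))) for i in range(k)]


def build_scale(values: np.ndarray, palette=DEFAULT_PALETTE, k: int = DEFAULT_BINS,
                balanced: bool = True, v_range: tuple[float, float] | None = None) -> ColorScale:
    """Build a color scale over the finite values of a matrix.

    Balanced: range [-M, M] with M = max|value|, k odd so the middle bin
    straddles 0.  Unbalanced: [min, max] split into k equal bins.  An
    explicit ``v_range`` overrides the data range (values outside it are
    later clamped to the end bins).  A degenerate all-equal range is
    expanded by +/-0.5 with a warning.
    """
    if k < 3:
        raise InputError(f"need at least 3 color bins, got {k}")
    if balanced and k % 2 == 0:
        raise InputError(f"balanced scale needs an odd bin count, got {k}")
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise EmptyInputError("no finite values to build a color scale from")

    if v_range is not None:
        lo, hi = float(v_range[0]), float(v_range[1])
    elif balanced:
        M = float(np.abs(finite).max())
        lo, hi = -M, M
    else:
        lo, hi = float(finite.min()), float(finite.max())
    if balanced and not np.isclose(lo, -hi):
        raise InputError("explicit range for a balanced scale must be symmetric about 0")
    if lo == hi:
        logger.warning("degenerate value range [%g, %g]; expanding by +/-0.5", lo, hi)
        lo, hi = lo - 0.5, hi + 0.5
    breakpoints = np.linspace(lo, hi, k + 1)
    return ColorScale(breakpoints=breakpoints, colors=_interpolate_palette(palette, k),
                      balanced=balanced, v_min=lo, v_max=hi)


def map_colors(values: np.ndarray, scale: ColorScale) -> np.ndarray:
    """Map each value to its bin index; missing values map to MISSING_INDEX.

    Bins are half-open [b_i, b_{i+1}) with the last bin closed; values
    outside the display range clamp to the end bins.
    """
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(scale.breakpoints, values, side="right") - 1
    idx = np.clip(idx, 0, scale.k - 1)
    out = np.where(np.isfinite(values), idx, MISSING_INDEX)
    return out.astype(int)


def index_to_hex(idx: np.ndarray, scale: ColorScale) -> np.ndarray:
    """Bin indices to hex colors (missing sentinel -> MISSING_COLOR)."""
    lut = np.array(list(scale.colors) + [MISSING_COLOR])
    return lut[np.asarray(idx)]
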