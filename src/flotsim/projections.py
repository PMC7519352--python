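"""Orthogonal stacking of line-scan frames and maximum intensity projection.

The 2-D comparator of the tomographic reconstruction is the MIP of the
raw "oblique stack": the camera frames stacked along the stage axis, with
frame axes (detector offset, along-line) serving as a z-proxy and y.  The
sampling is slanted relative to the true tissue axes; an optional shear
correction re-indexes each offset row along x by offset * cot(oblique
angle) to map the oblique sampling onto orthogonal axes (OFF by default
for the comparator, which uses the raw stacked frames).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import MeasurementStack


@dataclass
class StackVolume:
    """Frames stacked along x; axes (x = frame index, z-proxy = offset, y)."""

    data: np.ndarray
    axes: tuple = ("x", "zproxy", "y")
    oblique_deg: float = 30.0
    shear_corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("stack volume must be 3-D")
        if np.any(self.data < 0):
            raise ValueError("stack volume must be nonnegative")


def orthogonal_stack(
    stack: MeasurementStack, shear_correct: bool = False
) -> StackVolume:
    """Stack the n_positions frames along x, masking the leakage column.

    With ``shear_correct`` each offset row is shifted along x by
    offset * cot(oblique_deg) (in stage steps) so an object imaged
    obliquely appears at constant x across offsets.
    """
    if stack.source_col is None:
        raise ValueError("source line is not registered on this stack")
    acq = stack.acq
    data = stack.frames.astype(np.float64).copy()
    data[:, stack.source_col, :] = 0.0
    if shear_correct:
        cot = 1.0 / math.tan(math.radians(acq.oblique_deg))
        offsets = acq.offset_positions - acq.offset_positions[stack.source_col]
        shifts = offsets * cot / acq.stage_step  # stage-step units along x
        out = np.empty_like(data)
        for j in range(data.shape[1]):
            out[:, j, :] = ndimage.shift(
                data[:, j, :], (-shifts[j], 0.0), order=1, mode="constant", cval=0.0
            )
        data = np.maximum(out, 0.0)
    return StackVolume(
        data,
        oblique_deg=acq.oblique_deg,
        shear_corrected=shear_correct,
        meta={"stage_step": acq.stage_step, "pixel_pitch": acq.pixel_pitch},
    )


def mip(volume, axis) -> np.ndarray:
    """Maximum intensity projection along one axis (name or index)."""
    if hasattr(volume, "values"):  # ReconstructionVolume
        data, axes = volume.values, ("x", "y", "z")
    elif isinstance(volume, StackVolume):
        data, axes = volume.data, volume.axes
    else:
        data, axes = np.asarray(volume), None
    if data.size == 0:
        raise ValueError("cannot project an empty volume")
    if isinstance(axis, str):
        if axes is None or axis not in axes:
            raise ValueError(f"unknown axis {axis!r} for this volume")
        axis = axes.index(axis)
    return data.max(axis=axis)


def mips(volume) -> dict:
    """The standard pair of projections along the X and Y directions."""
    return {"x": mip(volume, 0), "y": mip(volume, "y" if not isinstance(volume, np.ndarray) else -1)}
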