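"""Diffusion-along-perivascular-space (ALPS) index.

The index contrasts diffusivity along the perivascular direction (the x
axis, perpendicular to both projection and association fiber tracts at the
level of the lateral ventricle body) with diffusivity across it:

    ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)

computed per hemisphere from ROI-mean diffusivities (mm^2/s) and reported
as the mean of the two sides.  Tensor fitting and template registration are
upstream, external steps; this stage consumes per-axis diffusivity maps or
pre-extracted ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AlpsInputs:
    """ROI-mean diffusivities for one hemisphere (all > 0, mm^2/s)."""

    dx_proj: float
    dy_proj: float
    dx_assoc: float
    dz_assoc: float

    def __post_init__(self):
        for name in ("dx_proj", "dy_proj", "dx_assoc", "dz_assoc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite diffusivity, got {v}")


def alps_index(inputs: AlpsInputs) -> float:
    """mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)."""
    return (inputs.dx_proj + inputs.dx_assoc) / (inputs.dy_proj + inputs.dz_assoc)


def bilateral_alps(left: float | None, right: float | None) -> float:
    """Mean of left and right hemisphere indices.

    A missing side makes the bilateral value missing (NaN) rather than
    silently falling back to the available side.
    """
    if left is None or right is None or not (np.isfinite(left) and np.isfinite(right)):
        return float("nan")
    return 0.5 * (left + right)


def extract_roi_diffusivities(diffusivity_maps: dict, roi_masks: dict) -> AlpsInputs:
    """ROI-mean diffusivities for one hemisphere.

    diffusivity_maps : {"x": 3D, "y": 3D, "z": 3D} per-axis diffusivity volumes
    roi_masks        : {"projection": 3D bool, "association": 3D bool}
    """
    for key in ("x", "y", "z"):
        if key not in diffusivity_maps:
            raise ValueError(f"missing diffusivity map {key!r}")
    for key in ("projection", "association"):
        if key not in roi_masks:
            raise ValueError(f"missing ROI mask {key!r}")
    shape = np.asarray(diffusivity_maps["x"]).shape

    def roi_mean(axis, roi):
        vol = np.asarray(diffusivity_maps[axis], dtype=float)
        m = np.asarray(roi_masks[roi], dtype=bool)
        if vol.shape != shape or m.shape != shape:
            raise ValueError("diffusivity maps and ROI masks are on different grids")
        if not m.any():
            raise ValueError(f"empty {roi} ROI")
        return float(vol[m].mean())

    return AlpsInputs(
        dx_proj=roi_mean("x", "projection"),
        dy_proj=roi_mean("y", "projection"),
        dx_assoc=roi_mean("x", "association"),
        dz_assoc=roi_mean("z", "association"),
    )
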