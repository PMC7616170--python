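"""Full-width-at-half-maximum PSI normalization and the layered shell model.

The pixel-signal-intensity (PSI) map expresses every in-mask voxel as a
percentage of a reference maximum taken over the LV myocardium, the
normalization underlying FWHM scar mapping: 50% is by construction the
"half maximum".  The layered shell model resamples the myocardium into
concentric triangulated surfaces from endocardium to epicardium,
mirroring the layer exports of clinical post-processing platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import LGEStack

__all__ = ["PSIMap", "ShellLayer", "LayeredShellModel", "compute_psi", "build_layered_model"]


@dataclass
class PSIMap:
    """Per-voxel normalized signal intensity in percent of the reference max.

    ``psi`` is NaN outside ``mask``; inside it lies in [0, 100], with
    values above the reference clipped to 100.
    """

    psi: np.ndarray
    mask: np.ndarray
    reference_max: float
    normalization_mode: str
    spacing: tuple[float, float, float]


@dataclass
class ShellLayer:
    vertices: np.ndarray   # (n_slices * n_rays, 3) mm
    faces: np.ndarray      # (m, 3) int triangles
    psi: np.ndarray        # (n_vertices,) percent


@dataclass
class LayeredShellModel:
    """Concentric surfaces from endocardium (layer 0) to epicardium."""

    layers: list[ShellLayer]
    n_slices: int
    n_rays: int

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def compute_psi(
    stack: LGEStack,
    mode: str = "robust_percentile",
    percentile: float = 98.0,
) -> PSIMap:
    """Normalize in-mask signal intensity to percent of a reference maximum.

    ``mode="global_max"`` uses the maximal in-mask SI (exact on
    noise-free phantoms); ``mode="robust_percentile"`` (default) uses
    the given percentile of in-mask SI, guarding against hot pixels.
    """
    mask = stack.myocardium_mask
    if not mask.any():
        raise ValueError("myocardium mask is empty")
    si = stack.image
    if np.any(si[mask] < 0):
        raise ValueError("signal intensity must be non-negative")
    in_mask = si[mask]
    if mode == "global_max":
        ref = float(in_mask.max())
    elif mode == "robust_percentile":
        ref = float(np.percentile(in_mask, percentile))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref <= 0:
        raise ValueError("reference maximum is zero: flat zero image")

    psi = np.full(si.shape, np.nan)
    psi[mask] = np.clip(100.0 * si[mask] / ref, 0.0, 100.0)
    return PSIMap(
        psi=psi,
        mask=mask,
        reference_max=ref,
        normalization_mode=mode,
        spacing=stack.spacing,
    )


def fill_outside_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace out-of-mask values by the nearest in-mask value.

    Used before trilinear sampling so interpolation at the mask edge
    never mixes in NaNs or background zeros.
    """
    out = np.array(values, dtype=float)
    if mask.all():
        return out
    _, idx = ndimage.distance_transform_edt(~mask, return_indices=True)
    return out[tuple(idx)]


def sample_trilinear(volume: np.ndarray, points_vox: np.ndarray) -> np.ndarray:
    """Trilinear sample of ``volume`` at fractional voxel coordinates (n, 3)."""
    return ndimage.map_coordinates(volume, points_vox.T, order=1, mode="nearest")


def build_layered_model(
    stack: LGEStack,
    psi: PSIMap,
    n_layers: int = 9,
    n_rays: int = 72,
) -> LayeredShellModel:
    """Resample the myocardium into ``n_layers`` concentric surfaces.

    On every slice the mask occupies, rays are cast from the slice
    centroid of the mask; the first and last mask crossing along a ray
    give the endocardial and epicardial radii.  Layer k sits at
    relative wall depth k/(n_layers-1); n_layers=2 returns the endo and
    epi surfaces themselves.  Per-vertex PSI is trilinear-interpolated
    from the PSI volume.

    Raises
    ------
    ValueError
        If a sampled ray crosses no myocardium on a slice the mask
        occupies (zero wall thickness); the message names the slice.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be at least 2")
    mask = stack.myocardium_mask
    sp = np.asarray(stack.spacing, float)
    slices = np.flatnonzero(mask.any(axis=(0, 1)))
    if slices.size == 0:
        raise ValueError("mask is empty")

    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    dr = 0.25 * min(sp[0], sp[1])
    r_max = np.hypot(mask.shape[0] * sp[0], mask.shape[1] * sp[1])
    radii = np.arange(0.0, r_max, dr)

    fracs = np.linspace(0.0, 1.0, n_layers)
    verts_per_layer: list[list[np.ndarray]] = [[] for _ in range(n_layers)]

    for k in slices:
        sl = mask[:, :, k]
        ci, cj = ndimage.center_of_mass(sl)
        cx, cy = ci * sp[0], cj * sp[1]
        for a in angles:
            xs = cx + radii * np.cos(a)
            ys = cy + radii * np.sin(a)
            ii = np.round(xs / sp[0]).astype(int)
            jj = np.round(ys / sp[1]).astype(int)
            inb = (ii >= 0) & (ii < sl.shape[0]) & (jj >= 0) & (jj < sl.shape[1])
            hit = np.zeros(radii.shape, dtype=bool)
            hit[inb] = sl[ii[inb], jj[inb]]
            if not hit.any():
                raise ValueError(
                    f"zero wall thickness along a ray on slice {k}: "
                    "mask does not form a shell there"
                )
            r_endo = radii[np.argmax(hit)]
            r_epi = radii[len(hit) - 1 - np.argmax(hit[::-1])]
            for li, f in enumerate(fracs):
                r = r_endo + f * (r_epi - r_endo)
                verts_per_layer[li].append(
                    np.array([cx + r * np.cos(a), cy + r * np.sin(a), k * sp[2]])
                )

    n_slices = slices.size
    faces = _ring_faces(n_slices, n_rays)
    psi_filled = fill_outside_mask(psi.psi, psi.mask)

    layers = []
    for li in range(n_layers):
        v = np.asarray(verts_per_layer[li])
        pts_vox = v / sp
        layer_psi = np.clip(sample_trilinear(psi_filled, pts_vox), 0.0, 100.0)
        layers.append(ShellLayer(vertices=v, faces=faces, psi=layer_psi))
    return LayeredShellModel(layers=layers, n_slices=n_slices, n_rays=n_rays)


def _ring_faces(n_slices: int, n_rays: int) -> np.ndarray:
    """Triangles connecting consecutive rings of ray vertices."""
    faces = []
    for s in range(n_slices - 1):
        base0 = s * n_rays
        base1 = (s + 1) * n_rays
        for a in range(n_rays):
            b = (a + 1) % n_rays
            faces.append((base0 + a, base1 + a, base0 + b))
            faces.append((base0 + b, base1 + a, base1 + b))
    return np.asarray(faces, dtype=int)
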