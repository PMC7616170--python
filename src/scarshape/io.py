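"""File I/O: NIfTI volumes, YAML phantom specs, CSV cohorts, VTK meshes.

NIfTI reading and writing goes through nibabel with a diagonal affine
carrying the voxel spacing.  Meshes and shell layers are written as
legacy ASCII VTK (unstructured grid with a cell label field, polydata
with a point "psi" scalar) — plain-text formats any VTK reader opens.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import ChannelSpec, CohortTable, LGEStack, PhantomSpec, ScarPatchSpec
from .lv_model import LayeredShellModel, PSIMap
from .classify import TissueLabelField, ThresholdConfig
from .mesh_interface import LabeledVolumeMesh

__all__ = [
    "save_volume",
    "load_volume",
    "save_stack",
    "load_stack",
    "save_psi",
    "load_psi",
    "save_labels",
    "phantom_spec_to_yaml",
    "phantom_spec_from_yaml",
    "save_cohort",
    "load_cohort",
    "write_vtk_mesh",
    "write_vtk_layers",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(data: np.ndarray, spacing, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(spacing)), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_stack(stack: LGEStack, out_dir: str | Path) -> dict[str, Path]:
    """Write image/mask (and, for phantoms, truth volumes) as NIfTI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    save_volume(stack.image.astype(np.float32), stack.spacing, out / "image.nii.gz")
    paths["image"] = out / "image.nii.gz"
    save_volume(stack.myocardium_mask.astype(np.uint8), stack.spacing, out / "mask.nii.gz")
    paths["mask"] = out / "mask.nii.gz"
    if stack.truth_labels is not None:
        save_volume(stack.truth_labels.astype(np.int8), stack.spacing, out / "truth_labels.nii.gz")
        paths["truth_labels"] = out / "truth_labels.nii.gz"
    if stack.truth_corridors is not None:
        save_volume(
            stack.truth_corridors.astype(np.int16), stack.spacing, out / "truth_corridors.nii.gz"
        )
        paths["truth_corridors"] = out / "truth_corridors.nii.gz"
    return paths


def load_stack(image_path: str | Path, mask_path: str | Path) -> LGEStack:
    image, spacing = load_volume(image_path)
    mask, mask_spacing = load_volume(mask_path)
    if not np.allclose(spacing, mask_spacing):
        raise ValueError("image and mask voxel spacings differ")
    return LGEStack(image=image, spacing=spacing, myocardium_mask=mask > 0)


def save_psi(psi: PSIMap, path: str | Path) -> None:
    save_volume(np.nan_to_num(psi.psi, nan=-1.0).astype(np.float32), psi.spacing, path)


def load_psi(path: str | Path, mask: Optional[np.ndarray] = None) -> PSIMap:
    vol, spacing = load_volume(path)
    if mask is None:
        mask = vol >= 0
    psi = np.where(mask, vol, np.nan)
    return PSIMap(
        psi=psi,
        mask=np.asarray(mask, bool),
        reference_max=float(np.nanmax(vol)),
        normalization_mode="loaded",
        spacing=spacing,
    )


def save_labels(field: TissueLabelField, path: str | Path) -> None:
    save_volume(field.labels.astype(np.int8), field.spacing, path)


def load_labels(path: str | Path, config: ThresholdConfig) -> TissueLabelField:
    vol, spacing = load_volume(path)
    labels = vol.astype(np.int8)
    return TissueLabelField(labels=labels, mask=labels >= 0, config=config, spacing=spacing)


# --------------------------------------------------------------------------
# Phantom spec YAML
# --------------------------------------------------------------------------

def phantom_spec_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(spec), sort_keys=False))


def phantom_spec_from_yaml(path: str | Path) -> PhantomSpec:
    raw = yaml.safe_load(Path(path).read_text())
    patches = []
    for p in raw.pop("scar_patches", []) or []:
        channels = tuple(ChannelSpec(**c) for c in p.pop("channels", []) or [])
        patches.append(ScarPatchSpec(channels=channels, **p))
    for key in ("grid_shape", "spacing", "endo_radii", "epi_radii", "si_levels", "lv_center"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return PhantomSpec(scar_patches=tuple(patches), **raw)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def save_cohort(cohort: CohortTable, path: str | Path) -> None:
    """CSV with a header row; generating-distribution metadata in a
    JSON sidecar next to it."""
    path = Path(path)
    cohort.table.to_csv(path, index=False)
    path.with_suffix(".meta.json").write_text(json.dumps(cohort.metadata, indent=2))


def load_cohort(path: str | Path) -> CohortTable:
    path = Path(path)
    table = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CohortTable(table=table, metadata=metadata)


# --------------------------------------------------------------------------
# VTK writers (legacy ASCII)
# --------------------------------------------------------------------------

def write_vtk_mesh(mesh: LabeledVolumeMesh, path: str | Path) -> None:
    """Legacy ASCII VTK unstructured grid with a 'tissue_label' cell field."""
    v, e = mesh.vertices, mesh.elements
    lines = [
        "# vtk DataFile Version 3.0",
        "scarshape labeled volumetric mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(v)} float",
    ]
    lines += [f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in v]
    lines.append(f"CELLS {len(e)} {len(e) * 5}")
    lines += [f"4 {a} {b} {c} {d}" for a, b, c, d in e]
    lines.append(f"CELL_TYPES {len(e)}")
    lines += ["10"] * len(e)  # VTK_TETRA
    lines += [
        f"CELL_DATA {len(e)}",
        "SCALARS tissue_label int 1",
        "LOOKUP_TABLE default",
    ]
    lines += [str(int(l)) for l in mesh.element_label]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_layers(model: LayeredShellModel, out_dir: str | Path) -> list[Path]:
    """One legacy ASCII VTK polydata file per shell layer, with a 'psi'
    point scalar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, layer in enumerate(model.layers):
        lines = [
            "# vtk DataFile Version 3.0",
            f"scarshape shell layer {i}",
            "ASCII",
            "DATASET POLYDATA",
            f"POINTS {len(layer.vertices)} float",
        ]
        lines += [f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in layer.vertices]
        lines.append(f"POLYGONS {len(layer.faces)} {len(layer.faces) * 4}")
        lines += [f"3 {a} {b} {c}" for a, b, c in layer.faces]
        lines += [
            f"POINT_DATA {len(layer.vertices)}",
            "SCALARS psi float 1",
            "LOOKUP_TABLE default",
        ]
        lines += [f"{x:.4f}" for x in layer.psi]
        p = out / f"layer_{i:02d}.vtk"
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return paths
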