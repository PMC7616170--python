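"""Conducting-corridor (channel / isthmus) detection.

A corridor is a connected border-zone region threading through scar
core — the potential reentry substrate.  Operationally: 26-connected
components of BZ voxels whose within-myocardium boundary (face-adjacent
non-BZ neighbours) is predominantly core rather than healthy tissue.
Two knobs control "predominantly": the minimum core fraction of the
boundary contacts (default 2/3) and a minimum component size (default
5 voxels) suppressing single-voxel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import BZ, CORE, HEALTHY
from .classify import MYOCARDIAL_DENSITY_G_PER_ML, TissueLabelField

__all__ = ["Corridor", "CorridorSet", "detect_corridors", "corridor_report"]


@dataclass
class Corridor:
    """One detected BZ channel."""

    voxel_indices: np.ndarray        # (n, 3) int
    mass_g: float
    core_contacts: int               # face-adjacent core neighbour pairs
    healthy_contacts: int            # face-adjacent healthy neighbour pairs

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])

    @property
    def core_contact_fraction(self) -> float:
        total = self.core_contacts + self.healthy_contacts
        return self.core_contacts / total if total else 0.0


@dataclass
class CorridorSet:
    """All corridors of one label field, in canonical order
    (ascending minimum linear voxel index)."""

    corridors: list[Corridor] = field(default_factory=list)
    label_volume: np.ndarray | None = None   # int ids 1..k, 0 elsewhere

    @property
    def total_count(self) -> int:
        return len(self.corridors)

    @property
    def total_mass_g(self) -> float:
        return float(sum(c.mass_g for c in self.corridors))


_FACE_SHIFTS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def detect_corridors(
    label_field: TissueLabelField,
    core_fraction_min: float = 2.0 / 3.0,
    min_voxels: int = 5,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> CorridorSet:
    """Find BZ components surrounded (mostly) by scar core.

    A 26-connected BZ component is a corridor iff its face-adjacent
    within-myocardium boundary contacts are core in proportion at least
    ``core_fraction_min`` and it has at least ``min_voxels`` voxels.
    A field without core (or without BZ) simply yields an empty set.
    Pure function of the label field; component order is canonical.
    """
    if not 0.0 < core_fraction_min <= 1.0:
        raise ValueError("core_fraction_min must be in (0, 1]")
    labels = label_field.labels
    bz = labels == BZ
    comp, n_comp = ndimage.label(bz, structure=np.ones((3, 3, 3), dtype=bool))

    # Count face-adjacent (core, healthy) neighbour pairs per component.
    core_counts = np.zeros(n_comp + 1, dtype=np.int64)
    healthy_counts = np.zeros(n_comp + 1, dtype=np.int64)
    for shift in _FACE_SHIFTS:
        nb = _shifted(labels, shift, fill=-1)
        src = comp[bz]
        nb_lab = nb[bz]
        np.add.at(core_counts, src[nb_lab == CORE], 1)
        np.add.at(healthy_counts, src[nb_lab == HEALTHY], 1)

    vox_ml = label_field.voxel_volume_mm3 / 1000.0
    ids = []
    for cid in range(1, n_comp + 1):
        total = core_counts[cid] + healthy_counts[cid]
        if total == 0:
            continue
        if core_counts[cid] / total < core_fraction_min:
            continue
        ids.append(cid)

    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=ids) if ids else []
    kept = [cid for cid, sz in zip(ids, sizes) if sz >= min_voxels]

    # Canonical order: ascending minimum linear voxel index.
    lin = np.arange(comp.size).reshape(comp.shape)
    corridors = []
    order = []
    for cid in kept:
        where = comp == cid
        order.append(int(lin[where].min()))
        idx = np.argwhere(where)
        corridors.append(
            Corridor(
                voxel_indices=idx,
                mass_g=idx.shape[0] * vox_ml * density,
                core_contacts=int(core_counts[cid]),
                healthy_contacts=int(healthy_counts[cid]),
            )
        )
    corridors = [c for _, c in sorted(zip(order, corridors), key=lambda t: t[0])]

    out_vol = np.zeros(labels.shape, dtype=np.int16)
    for i, c in enumerate(corridors, start=1):
        out_vol[tuple(c.voxel_indices.T)] = i
    return CorridorSet(corridors=corridors, label_volume=out_vol)


def _shifted(a: np.ndarray, shift: tuple[int, int, int], fill: int) -> np.ndarray:
    out = np.full_like(a, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift):
        if s > 0:
            src[ax], dst[ax] = slice(s, None), slice(None, -s)
        elif s < 0:
            src[ax], dst[ax] = slice(None, s), slice(-s, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def corridor_report(cset: CorridorSet) -> pd.DataFrame:
    """Per-corridor rows plus a TOTAL row (count and summed mass)."""
    rows = [
        {
            "corridor_id": i,
            "n_voxels": c.n_voxels,
            "mass_g": c.mass_g,
            "core_contact_fraction": c.core_contact_fraction,
            "healthy_contacts": c.healthy_contacts,
        }
        for i, c in enumerate(cset.corridors, start=1)
    ]
    rows.append(
        {
            "corridor_id": "TOTAL",
            "n_voxels": sum(c.n_voxels for c in cset.corridors),
            "mass_g": cset.total_mass_g,
            "core_contact_fraction": np.nan,
            "healthy_contacts": sum(c.healthy_contacts for c in cset.corridors),
        }
    )
    return pd.DataFrame(rows)
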