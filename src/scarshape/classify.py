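"""Tissue classification of PSI maps and mass quantification.

A threshold configuration (t_low, t_high) in PSI percent partitions the
myocardium into healthy (< t_low), border zone ([t_low, t_high], closed
interval) and scar core (> t_high).  Masses follow from voxel counts at
a constant myocardial density, so border-zone plus core mass equals the
total enhancement exactly and the three classes partition the total
myocardial mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import BZ, CORE, HEALTHY
from .lv_model import PSIMap

__all__ = [
    "ThresholdConfig",
    "TissueLabelField",
    "MassReport",
    "DEFAULT_CONFIGS",
    "classify_psi",
    "quantify_masses",
    "MYOCARDIAL_DENSITY_G_PER_ML",
]

#: Standard myocardial tissue density.
MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass(frozen=True)
class ThresholdConfig:
    """A PSI band (percent) delimiting border zone from healthy and core."""

    t_low: float
    t_high: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.t_low < self.t_high < 100.0:
            raise ValueError("thresholds must satisfy 0 < t_low < t_high < 100")
        if not self.name:
            object.__setattr__(self, "name", f"PSI {self.t_low:g}-{self.t_high:g}")


#: The four clinical configurations, narrowest BZ band first.
DEFAULT_CONFIGS = (
    ThresholdConfig(45.0, 55.0, "45-55"),
    ThresholdConfig(40.0, 60.0, "40-60"),
    ThresholdConfig(35.0, 65.0, "35-65"),
    ThresholdConfig(30.0, 70.0, "30-70"),
)


@dataclass
class TissueLabelField:
    """Per-voxel tissue label under one threshold configuration.

    ``labels`` holds {0 healthy, 1 BZ, 2 core} inside the mask and -1
    outside it.
    """

    labels: np.ndarray
    mask: np.ndarray
    config: ThresholdConfig
    spacing: tuple[float, float, float]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels[self.mask] == label))


@dataclass(frozen=True)
class MassReport:
    """Tissue masses in grams under one threshold configuration.

    ``total_enhancement_g`` is bz_g + core_g by construction (exact).
    """

    healthy_g: float
    bz_g: float
    core_g: float
    density: float = MYOCARDIAL_DENSITY_G_PER_ML

    @property
    def total_enhancement_g(self) -> float:
        return self.bz_g + self.core_g

    @property
    def total_myocardium_g(self) -> float:
        return self.healthy_g + self.total_enhancement_g


def classify_psi(psi: PSIMap, config: ThresholdConfig) -> TissueLabelField:
    """Threshold a PSI map into healthy / border zone / core.

    Voxels exactly at t_low or t_high are border zone (closed BZ
    interval).  Pure per-voxel operation: idempotent and independent of
    visiting order.
    """
    labels = np.full(psi.psi.shape, -1, dtype=np.int8)
    vals = psi.psi[psi.mask]
    lab = np.full(vals.shape, HEALTHY, dtype=np.int8)
    lab[(vals >= config.t_low) & (vals <= config.t_high)] = BZ
    lab[vals > config.t_high] = CORE
    labels[psi.mask] = lab
    return TissueLabelField(labels=labels, mask=psi.mask, config=config, spacing=psi.spacing)


def quantify_masses(
    field: TissueLabelField,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> MassReport:
    """Convert voxel counts to grams: count x voxel volume (mL) x density."""
    if density <= 0:
        raise ValueError("density must be positive")
    vox_ml = field.voxel_volume_mm3 / 1000.0
    return MassReport(
        healthy_g=field.count(HEALTHY) * vox_ml * density,
        bz_g=field.count(BZ) * vox_ml * density,
        core_g=field.count(CORE) * vox_ml * density,
        density=density,
    )
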