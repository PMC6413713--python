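"""Core domain containers for the perfusion / vascular-reactivity pipeline.

Conventions
-----------
* All grids live in 0-based voxel-index space; no affine resampling is
  performed anywhere in the package.  Atlas labels travel with the data,
  replacing manual ROI placement.
* Repetition indices in contrast-enhanced series are 1-based (repetition 1
  is the first post-contrast image), matching scanner bookkeeping.
* Standard deviations reported anywhere are sample (n-1) SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: ROI vocabulary for the arterial-spin-labeling (CBF) analysis.
ASL_REGIONS: tuple[str, ...] = ("cortex", "hippocampus", "thalamus")

#: ROI vocabulary for the cerebrovascular-reactivity (CBV) analysis.
CVR_REGIONS: tuple[str, ...] = (
    "motor_cortex",
    "sensory_cortex",
    "striatum",
    "hippocampus",
    "thalamus",
    "cerebellum",
)

#: Union of both ROI sets, in canonical label order (label i+1 = REGIONS[i]).
REGIONS: tuple[str, ...] = (
    "cortex",
    "motor_cortex",
    "sensory_cortex",
    "striatum",
    "hippocampus",
    "thalamus",
    "cerebellum",
)

#: Pseudo-region meaning "all labeled voxels"; not an atlas label.
WHOLE_BRAIN = "whole_brain"

GENOTYPES = ("NTL", "arcAb")
TREATMENTS = ("water", "noscapine")
SEXES = ("F", "M")


@dataclass
class Volume3D:
    """A 3-D scalar grid with voxel spacing metadata."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    identifier: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected 3 spatial dimensions, got {self.values.ndim}"
            )
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class LabelAtlas:
    """Integer region labels on a grid; 0 is background.

    ``region_names`` maps every non-zero label to a region name.  Regions
    are disjoint by construction (one label per voxel).
    """

    labels: np.ndarray
    region_names: Mapping[int, str]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.region_names)
        if missing:
            raise ValueError(f"labels without region names: {sorted(missing)}")
        self.region_names = dict(self.region_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.region_names.values())

    def label_of(self, region: str) -> int:
        for lab, name in self.region_names.items():
            if name == region:
                return lab
        raise KeyError(
            f"unknown region {region!r}; available: "
            f"{sorted(self.region_names.values()) + [WHOLE_BRAIN]}"
        )


@dataclass
class AslAcquisition:
    """Paired selective / global inversion-recovery series for one subject.

    Both series are sampled on the same, strictly increasing inversion-time
    grid; at least three inversion times are required for the 3-parameter
    magnitude-IR fit to be identifiable.
    """

    selective_series: list[Volume3D]
    global_series: list[Volume3D]
    inversion_times_s: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.inversion_times_s = np.asarray(self.inversion_times_s, dtype=float)
        if self.inversion_times_s.size < 3:
            raise ValueError("need >= 3 inversion times")
        if np.any(np.diff(self.inversion_times_s) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        if len(self.selective_series) != self.inversion_times_s.size:
            raise ValueError("selective series length != number of TIs")
        if len(self.global_series) != self.inversion_times_s.size:
            raise ValueError("global series length != number of TIs")
        shapes = {v.shape for v in self.selective_series + self.global_series}
        if len(shapes) != 1:
            raise ValueError("all volumes must share one shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.selective_series[0].shape


@dataclass
class T1MapPair:
    """Fitted T1 maps (seconds) from selective and global inversion."""

    t1_selective_s: Volume3D
    t1_global_s: Volume3D
    fit_residual: Volume3D | None = None


@dataclass(frozen=True)
class CbfConstants:
    """Constants of the two-T1 CBF quantification.

    ``lambda_partition`` is the blood/tissue water partition coefficient
    (0.9 ml/g), ``t1_blood_s`` the blood T1 at 7 T (2.007 s), and
    ``output_scale`` converts ml·g^-1·s^-1 to ml/100 g/min (6000).
    """

    lambda_partition: float = 0.9
    t1_blood_s: float = 2.007
    output_scale: float = 6000.0

    def __post_init__(self) -> None:
        if self.lambda_partition <= 0 or self.t1_blood_s <= 0:
            raise ValueError("constants must be positive")


@dataclass
class CvrAcquisition:
    """Contrast-enhanced signal time series for one subject.

    ``pre_contrast`` holds the baseline (Spre) scans acquired before the
    blood-pool contrast agent; ``main_series`` the post-contrast series,
    with the vasodilator given after 1-based repetition ``acz_rep``.
    Temporal resolution ``dt_s`` is seconds per repetition.
    """

    pre_contrast: list[Volume3D]
    main_series: list[Volume3D]
    dt_s: float = 40.0
    acz_rep: int = 30
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.pre_contrast) < 2:
            raise ValueError("need >= 2 pre-contrast scans")
        if len(self.main_series) <= self.acz_rep:
            raise ValueError("main series must extend past the stimulus")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        shapes = {v.shape for v in self.pre_contrast + self.main_series}
        if len(shapes) != 1:
            raise ValueError("all volumes must share one shape")

    @property
    def n_rep(self) -> int:
        return len(self.main_series)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.main_series[0].shape

    def times_min(self) -> np.ndarray:
        """Time axis of the main series in minutes relative to the stimulus.

        Repetition r (1-based) maps to (r - acz_rep) * dt_s / 60; negative
        before the vasodilator, 0 at the stimulus repetition itself.
        """
        reps = np.arange(1, self.n_rep + 1)
        return (reps - self.acz_rep) * self.dt_s / 60.0


@dataclass
class CvrResult:
    """Per-region vascular-reactivity summary for one subject."""

    subject_id: str
    region: str
    cbv0: float
    cbv0_negative: bool
    times_min: np.ndarray
    dcbv_pct: np.ndarray
    slope_a: float
    intercept_b: float
    corr_r: float
    late_dcbv_pct: float
    n_clipped: int
    excluded: bool = False


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    genotype: str
    treatment: str
    sex: str = "F"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")

    @property
    def group(self) -> str:
        return group_name(self.genotype, self.treatment)


def group_name(genotype: str, treatment: str) -> str:
    """Canonical group label for a genotype x treatment cell."""
    return genotype if treatment == "water" else f"{genotype}_noscapine"


#: The four study groups in reporting order.
GROUPS: tuple[str, ...] = (
    "NTL",
    "NTL_noscapine",
    "arcAb",
    "arcAb_noscapine",
)


def group_factors(group: str) -> tuple[str, str]:
    """Invert :func:`group_name` back to (genotype, treatment)."""
    for g in GENOTYPES:
        for t in TREATMENTS:
            if group_name(g, t) == group:
                return g, t
    raise ValueError(f"unknown group {group!r}")
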