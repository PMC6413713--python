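"""Synthetic phantoms, acquisitions and cohorts with known ground truth.

The generator emulates the statistical structure of a four-group mouse
study (non-transgenic littermates vs. an amyloidosis transgenic line,
untreated vs. drug-treated): box-shaped ROIs on a digital phantom,
selective/global inversion-recovery series whose T1 pair encodes a
regional CBF map, and a steady-state contrast-enhanced time series whose
post-stimulus kinetics follow a square-root-linear CBV response.  All
randomness flows from explicit seeds via ``numpy.random.SeedSequence``
spawning, so identical (spec, seed) give bit-identical outputs.

Magnitude images carry Rician noise: independent Gaussian noise of SD
``noise_sigma`` on each quadrature channel before the magnitude is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    ASL_REGIONS,
    CVR_REGIONS,
    GROUPS,
    REGIONS,
    AslAcquisition,
    CbfConstants,
    CvrAcquisition,
    LabelAtlas,
    SubjectRecord,
    Volume3D,
    group_factors,
)

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

_DEFAULT_BOXES: dict[str, Box] = {
    "cortex": ((6, 42), (6, 12), (1, 7)),
    "motor_cortex": ((6, 20), (14, 20), (1, 7)),
    "sensory_cortex": ((24, 38), (14, 20), (1, 7)),
    "striatum": ((6, 20), (22, 28), (1, 7)),
    "hippocampus": ((24, 38), (22, 28), (1, 7)),
    "thalamus": ((6, 20), (30, 36), (1, 7)),
    "cerebellum": ((24, 38), (30, 36), (1, 7)),
}

_SMALL_BOXES: dict[str, Box] = {
    "cortex": ((2, 14), (2, 4), (1, 3)),
    "motor_cortex": ((2, 8), (5, 7), (1, 3)),
    "sensory_cortex": ((8, 14), (5, 7), (1, 3)),
    "striatum": ((2, 8), (8, 10), (1, 3)),
    "hippocampus": ((8, 14), (8, 10), (1, 3)),
    "thalamus": ((2, 8), (11, 13), (1, 3)),
    "cerebellum": ((8, 14), (11, 13), (1, 3)),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the digital phantom: grid shape and per-region boxes.

    Boxes are half-open index ranges per axis.  Regions must be disjoint
    and hold at least 8 voxels each.
    """

    shape: tuple[int, int, int] = (48, 48, 8)
    boxes: Mapping[str, Box] = field(default_factory=lambda: dict(_DEFAULT_BOXES))
    baseline: float = 100.0
    brain_box: Box | None = None
    voxel_size_mm: tuple[float, float, float] = (0.15, 0.2, 1.0)

    @staticmethod
    def small() -> "PhantomSpec":
        """Reduced 16x16x4 phantom for Monte-Carlo work."""
        return PhantomSpec(
            shape=(16, 16, 4),
            boxes=dict(_SMALL_BOXES),
            brain_box=((1, 15), (1, 15), (0, 4)),
        )

    def region_voxel_count(self, region: str) -> int:
        (x0, x1), (y0, y1), (z0, z1) = self.boxes[region]
        return (x1 - x0) * (y1 - y0) * (z1 - z0)


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(a, b) for a, b in box)  # type: ignore[return-value]


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[Volume3D, LabelAtlas]:
    """Build the anatomy volume and label atlas from a phantom spec.

    Anatomy is ``baseline`` inside the brain box (default: everything but
    a one-voxel in-plane rim) and 0 outside.  Overlapping region boxes or
    regions smaller than 8 voxels are rejected.
    """
    labels = np.zeros(spec.shape, dtype=np.int32)
    names: dict[int, str] = {}
    # canonical label order keeps label->region stable across specs
    ordered = [r for r in REGIONS if r in spec.boxes] + [
        r for r in spec.boxes if r not in REGIONS
    ]
    for i, region in enumerate(ordered, start=1):
        box = spec.boxes[region]
        sl = _box_slices(box)
        if np.any(labels[sl] != 0):
            raise ValueError(f"region box {region!r} overlaps an earlier region")
        if spec.region_voxel_count(region) < 8:
            raise ValueError(f"region {region!r} smaller than 8 voxels")
        labels[sl] = i
        names[i] = region

    anatomy = np.zeros(spec.shape, dtype=float)
    if spec.brain_box is not None:
        anatomy[_box_slices(spec.brain_box)] = spec.baseline
    else:
        nx, ny, _ = spec.shape
        anatomy[
            min(4, nx // 8) : nx - min(4, nx // 8),
            min(4, ny // 8) : ny - min(4, ny // 8),
            :,
        ] = spec.baseline
    vol = Volume3D(anatomy, spec.voxel_size_mm, "phantom_anatomy")
    atlas = LabelAtlas(labels, names, spec.voxel_size_mm)
    return vol, atlas


def rician(true_signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of ``true_signal`` corrupted by complex Gaussian noise."""
    if sigma == 0:
        return np.abs(np.asarray(true_signal, dtype=float))
    s = np.asarray(true_signal, dtype=float)
    return np.hypot(s + rng.normal(0.0, sigma, s.shape), rng.normal(0.0, sigma, s.shape))


# ---------------------------------------------------------------------------
# ASL: inversion-recovery pair encoding a CBF map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AslTruth:
    """Ground truth for one subject's perfusion acquisition.

    ``cbf`` holds per-region true CBF in ml/100 g/min; the selective T1 is
    derived per region by inverting the two-T1 perfusion relation
    1/T1_sel = 1/T1_glob + CBF / (scale * lambda * T1_glob / T1_blood).
    ``inversion_efficiency`` is the factor on the recovering term (2 for a
    perfect inversion).
    """

    cbf: Mapping[str, float]
    t1_global_s: float = 1.70
    m0: float = 100.0
    noise_sigma: float = 2.0
    inversion_efficiency: float = 2.0
    constants: CbfConstants = CbfConstants()

    def t1_selective_s(self, region: str) -> float:
        c = self.constants
        rate = 1.0 / self.t1_global_s + self.cbf[region] / (
            c.output_scale * c.lambda_partition * (self.t1_global_s / c.t1_blood_s)
        )
        if rate <= 0:
            raise ValueError(
                f"region {region!r}: CBF {self.cbf[region]} implies non-positive "
                "selective relaxation rate"
            )
        return 1.0 / rate


def default_inversion_times(n: int = 8) -> np.ndarray:
    """Log-spaced inversion times, 0.1-8 s."""
    return np.geomspace(0.1, 8.0, n)


def _ir_signal(m0: float, t1: float, tis: np.ndarray, eff: float) -> np.ndarray:
    return m0 * (1.0 - eff * np.exp(-tis / t1))


def simulate_asl(
    truth: AslTruth,
    atlas: LabelAtlas,
    inversion_times_s: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sim",
) -> AslAcquisition:
    """Generate a selective/global magnitude inversion-recovery pair.

    Per labeled voxel the signed signal is M0 (1 - eff * exp(-TI/T1)) with
    the regional T1 (selective or global); the stored images are Rician
    magnitudes.  Unlabeled voxels carry pure noise.
    """
    tis = (
        default_inversion_times()
        if inversion_times_s is None
        else np.asarray(inversion_times_s, dtype=float)
    )
    missing = [r for r in atlas.names if r not in truth.cbf]
    if missing:
        raise ValueError(f"truth lacks CBF for regions: {missing}")
    t1_span = truth.t1_global_s  # selective T1 is always <= global
    if tis.size < 3 or tis.min() > 0.1 * t1_span or tis.max() < 3.0 * t1_span:
        raise ValueError("inversion times must cover >= 3 points spanning the T1 range")

    rng = np.random.default_rng(seed)
    t1_maps = {"selective": np.full(atlas.shape, np.nan), "global": np.full(atlas.shape, np.nan)}
    for lab, region in atlas.region_names.items():
        m = atlas.labels == lab
        t1_maps["selective"][m] = truth.t1_selective_s(region)
        t1_maps["global"][m] = truth.t1_global_s

    series: dict[str, list[Volume3D]] = {"selective": [], "global": []}
    for kind in ("selective", "global"):
        t1 = t1_maps[kind]
        inside = np.isfinite(t1)
        t1_safe = np.where(inside, t1, 1.0)
        for ti in tis:
            signed = np.where(
                inside,
                truth.m0 * (1.0 - truth.inversion_efficiency * np.exp(-ti / t1_safe)),
                0.0,
            )
            noisy = rician(signed, truth.noise_sigma, rng)
            series[kind].append(Volume3D(noisy, atlas.voxel_size_mm, f"{subject_id}_{kind}_TI{ti:.3f}"))
    return AslAcquisition(series["selective"], series["global"], tis, subject_id)


# ---------------------------------------------------------------------------
# CVR: steady-state contrast series with sqrt-linear response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CvrTruth:
    """Ground truth for one subject's contrast-enhanced acquisition.

    Per region: baseline blood volume ``cbv0`` (> 0, the log signal drop
    after contrast), and the response parameterization
    sqrt(dCBV%) = a * t + b for post-stimulus time t in minutes.
    ``response_sign`` = -1 simulates a contrast failure (signal rising
    after the stimulus), producing negative apparent dCBV%.
    """

    cbv0: Mapping[str, float]
    slope_a: Mapping[str, float]
    intercept_b: Mapping[str, float]
    spre: float = 100.0
    noise_sigma: float = 2.0
    response_sign: int = 1


def simulate_cvr(
    truth: CvrTruth,
    atlas: LabelAtlas,
    n_pre: int = 8,
    n_rep: int = 100,
    acz_rep: int = 30,
    dt_s: float = 40.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sim",
) -> CvrAcquisition:
    """Generate the pre-contrast block and post-contrast main series.

    Noiseless model per region: pre-contrast scans at Spre; repetitions
    1..acz_rep at the post-contrast steady state S0 = Spre * exp(-CBV0);
    repetitions acz_rep+1..n_rep at S(t) = S0 * (S0/Spre)^(dCBV%(t)/100)
    with dCBV%(t) = (a t + b)^2 and t = (rep - acz_rep) * dt / 60 minutes.
    """
    regions = atlas.names
    for r in regions:
        if r not in truth.cbv0 or r not in truth.slope_a or r not in truth.intercept_b:
            raise ValueError(f"truth lacks CVR parameters for region {r!r}")
        if truth.cbv0[r] <= 0:
            raise ValueError(
                f"region {r!r}: CBV0 must be > 0 (contrast must darken the signal)"
            )
    t_end = (n_rep - acz_rep) * dt_s / 60.0
    for r in regions:
        if truth.intercept_b[r] < 0 or truth.slope_a[r] * t_end + truth.intercept_b[r] < 0:
            raise ValueError(f"region {r!r}: a*t+b goes negative on the simulated window")

    rng = np.random.default_rng(seed)
    times = (np.arange(1, n_rep + 1) - acz_rep) * dt_s / 60.0

    # per-region noiseless signal trajectories
    level = {}
    for lab, r in atlas.region_names.items():
        s0 = truth.spre * np.exp(-truth.cbv0[r])
        dcbv = np.where(
            times > 0,
            truth.response_sign * (truth.slope_a[r] * np.clip(times, 0, None) + truth.intercept_b[r]) ** 2,
            0.0,
        )
        level[lab] = s0 * (s0 / truth.spre) ** (dcbv / 100.0)

    def volume_at(idx: int | None) -> np.ndarray:
        signal = np.zeros(atlas.shape)
        for lab in atlas.region_names:
            m = atlas.labels == lab
            signal[m] = truth.spre if idx is None else level[lab][idx]
        return rician(signal, truth.noise_sigma, rng)

    pre = [
        Volume3D(volume_at(None), atlas.voxel_size_mm, f"{subject_id}_pre{i+1}")
        for i in range(n_pre)
    ]
    main = [
        Volume3D(volume_at(i), atlas.voxel_size_mm, f"{subject_id}_rep{i+1}")
        for i in range(n_rep)
    ]
    return CvrAcquisition(pre, main, dt_s, acz_rep, subject_id)


# ---------------------------------------------------------------------------
# Cohort: four genotype x treatment groups with between-subject variation
# ---------------------------------------------------------------------------

# Group CBF (ml/100 g/min): cortex and thalamus from the study's perfusion
# results; hippocampus (not printed) set between them with a mild,
# non-significant transgenic reduction.  Treated NTLs track untreated NTLs.
_CBF_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "NTL": {"cortex": (165.4, 31.1), "hippocampus": (180.0, 35.0), "thalamus": (200.5, 38.4)},
    "NTL_noscapine": {"cortex": (165.4, 31.1), "hippocampus": (180.0, 35.0), "thalamus": (200.5, 38.4)},
    "arcAb": {"cortex": (123.0, 40.8), "hippocampus": (170.0, 40.0), "thalamus": (154.1, 61.1)},
    "arcAb_noscapine": {"cortex": (167.6, 33.9), "hippocampus": (178.0, 36.0), "thalamus": (196.3, 43.8)},
}

# Group sqrt-linear response (slope a in sqrt(%)/min, intercept b in
# sqrt(%)): the study's regression table, caudate nucleus mapped to
# striatum.  The printed +/- values are adopted as between-subject SDs.
_CVR_DEFAULTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "NTL": {
        "motor_cortex": {"a": (0.061, 0.002), "b": (2.178, 0.056)},
        "sensory_cortex": {"a": (0.064, 0.003), "b": (3.120, 0.087)},
        "hippocampus": {"a": (0.045, 0.002), "b": (2.451, 0.047)},
        "thalamus": {"a": (0.042, 0.002), "b": (2.549, 0.063)},
        "striatum": {"a": (0.054, 0.001), "b": (1.826, 0.032)},
        "cerebellum": {"a": (0.035, 0.003), "b": (3.342, 0.075)},
    },
    "NTL_noscapine": {
        "motor_cortex": {"a": (0.066, 0.002), "b": (1.747, 0.047)},
        "sensory_cortex": {"a": (0.069, 0.004), "b": (3.383, 0.096)},
        "hippocampus": {"a": (0.047, 0.002), "b": (2.127, 0.055)},
        "thalamus": {"a": (0.078, 0.003), "b": (2.669, 0.090)},
        "striatum": {"a": (0.065, 0.001), "b": (1.327, 0.034)},
        "cerebellum": {"a": (0.045, 0.003), "b": (2.946, 0.075)},
    },
    "arcAb": {
        "motor_cortex": {"a": (0.048, 0.001), "b": (1.400, 0.023)},
        "sensory_cortex": {"a": (0.038, 0.002), "b": (3.164, 0.058)},
        "hippocampus": {"a": (0.050, 0.002), "b": (2.503, 0.048)},
        "thalamus": {"a": (0.049, 0.002), "b": (2.690, 0.044)},
        "striatum": {"a": (0.059, 0.002), "b": (1.376, 0.043)},
        "cerebellum": {"a": (0.035, 0.001), "b": (2.619, 0.033)},
    },
    "arcAb_noscapine": {
        "motor_cortex": {"a": (0.057, 0.001), "b": (2.379, 0.037)},
        "sensory_cortex": {"a": (0.054, 0.003), "b": (2.989, 0.082)},
        "hippocampus": {"a": (0.050, 0.002), "b": (2.959, 0.066)},
        "thalamus": {"a": (0.058, 0.002), "b": (2.731, 0.062)},
        "striatum": {"a": (0.053, 0.002), "b": (1.848, 0.045)},
        "cerebellum": {"a": (0.037, 0.002), "b": (2.429, 0.050)},
    },
}

_GROUP_N = {"NTL": 8, "NTL_noscapine": 9, "arcAb": 9, "arcAb_noscapine": 11}
_GROUP_SEX = {  # females, males per group
    "NTL": (4, 4),
    "NTL_noscapine": (7, 2),
    "arcAb": (5, 4),
    "arcAb_noscapine": (4, 7),
}
_CBV0_DEFAULT = (0.5, 0.05)


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes and per-group, per-region truth distributions.

    Between-subject variation is Gaussian on the regional truths,
    truncated at 0 by rejection sampling; scan noise is separate
    (``asl_noise_sigma`` / ``cvr_noise_sigma`` on 100 a.u. signals).
    """

    group_n: Mapping[str, int] = field(default_factory=lambda: dict(_GROUP_N))
    group_sex: Mapping[str, tuple[int, int]] = field(default_factory=lambda: dict(_GROUP_SEX))
    cbf: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _CBF_DEFAULTS
    )
    cvr: Mapping[str, Mapping[str, Mapping[str, tuple[float, float]]]] = field(
        default_factory=lambda: _CVR_DEFAULTS
    )
    cbv0: tuple[float, float] = _CBV0_DEFAULT
    asl_noise_sigma: float = 2.0
    cvr_noise_sigma: float = 2.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    t1_global_s: float = 1.70

    def __post_init__(self) -> None:
        for g, n in self.group_n.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2, got {n}")


@dataclass
class SubjectBundle:
    record: SubjectRecord
    asl: AslAcquisition | None
    cvr: CvrAcquisition | None
    asl_truth: AslTruth | None
    cvr_truth: CvrTruth | None


@dataclass
class CohortBundle:
    subjects: list[SubjectBundle]
    atlas: LabelAtlas
    anatomy: Volume3D
    truth_cbf: pd.DataFrame
    truth_cvr: pd.DataFrame

    @property
    def records(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian draw truncated at 0 by rejection (exact, seeded)."""
    if sd == 0:
        if mean < 0:
            raise ValueError("degenerate truncated normal with negative mean")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def _subject_cbf_truth(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> dict[str, float]:
    """Draw per-region CBF for one subject; regions outside the perfusion
    ROI set inherit the group's cortex distribution."""
    draws: dict[str, float] = {}
    gp = spec.cbf[group]
    for region in REGIONS:
        mean, sd = gp.get(region, gp["cortex"])
        draws[region] = _truncated_normal(rng, mean, sd)
    return draws


def simulate_cohort(
    spec: CohortSpec = CohortSpec(),
    seed: int | np.random.SeedSequence = 0,
    modalities: Iterable[str] = ("asl", "cvr"),
    inversion_times_s: np.ndarray | None = None,
) -> CohortBundle:
    """Generate the full four-group study with per-subject ground truth.

    Child seeds are spawned deterministically from the master seed (one
    per subject, then one per modality), so any subset of modalities is
    reproducible independently of the others.
    """
    modalities = tuple(modalities)
    anatomy, atlas = make_phantom(spec.phantom)
    master = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    n_total = sum(spec.group_n.values())
    subject_seqs = master.spawn(n_total)

    subjects: list[SubjectBundle] = []
    cbf_rows, cvr_rows = [], []
    idx = 0
    for group in GROUPS:
        if group not in spec.group_n:
            continue
        genotype, treatment = group_factors(group)
        n = spec.group_n[group]
        n_f, n_m = spec.group_sex.get(group, (-1, -1))
        if n_f + n_m != n:  # custom n without matching counts: split evenly
            n_f, n_m = n // 2, n - n // 2
        sexes = ["F"] * n_f + ["M"] * n_m
        for j in range(spec.group_n[group]):
            sid = f"{group}_{j+1:02d}"
            record = SubjectRecord(sid, genotype, treatment, sexes[j])
            seq = subject_seqs[idx]
            idx += 1
            truth_rng_seq, asl_seq, cvr_seq = seq.spawn(3)
            rng = np.random.default_rng(truth_rng_seq)

            cbf_truth = _subject_cbf_truth(spec, group, rng)
            cvr_group = spec.cvr[group]
            a = {r: _truncated_normal(rng, *cvr_group[r]["a"]) for r in CVR_REGIONS}
            b = {r: _truncated_normal(rng, *cvr_group[r]["b"]) for r in CVR_REGIONS}
            cbv0 = {r: _truncated_normal(rng, *spec.cbv0) for r in CVR_REGIONS}
            # regions outside the CVR ROI set reuse hippocampal kinetics so
            # every labeled voxel has a defined trajectory
            for r in REGIONS:
                a.setdefault(r, a["hippocampus"])
                b.setdefault(r, b["hippocampus"])
                cbv0.setdefault(r, cbv0["hippocampus"])

            asl_truth = AslTruth(
                cbf_truth, t1_global_s=spec.t1_global_s, noise_sigma=spec.asl_noise_sigma
            )
            cvr_truth = CvrTruth(
                cbv0, a, b, noise_sigma=spec.cvr_noise_sigma
            )
            asl_acq = (
                simulate_asl(asl_truth, atlas, inversion_times_s, asl_seq, sid)
                if "asl" in modalities
                else None
            )
            cvr_acq = (
                simulate_cvr(cvr_truth, atlas, seed=cvr_seq, subject_id=sid)
                if "cvr" in modalities
                else None
            )
            subjects.append(
                SubjectBundle(record, asl_acq, cvr_acq, asl_truth, cvr_truth)
            )
            for region in ASL_REGIONS:
                cbf_rows.append(
                    {"subject_id": sid, "group": group, "region": region,
                     "metric": "cbf_true", "value": cbf_truth[region]}
                )
            for region in CVR_REGIONS:
                for metric, table in (("slope_a_true", a), ("intercept_b_true", b), ("cbv0_true", cbv0)):
                    cvr_rows.append(
                        {"subject_id": sid, "group": group, "region": region,
                         "metric": metric, "value": table[region]}
                    )

    return CohortBundle(
        subjects,
        atlas,
        anatomy,
        pd.DataFrame(cbf_rows),
        pd.DataFrame(cvr_rows),
    )
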