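"""Synthetic, pre-aligned R1 phantom cohorts.

The phantom emulates the statistical structure the downstream analysis
assumes, without any MR acquisition physics: nested ellipsoids stand in for
anatomy (background / cortical GM shell / WM core / two globus-pallidus
blobs), every subject lives on the same grid (registration is assumed done),
per-tissue baseline R1 follows published 3T magnitudes (WM 1.07 s^-1, GP
1.10 s^-1), R1 varies quadratically with age around a reference age, and
between-subject residual variation is a spatially smooth Gaussian field.
Welder subjects may carry focal spherical R1 elevations that mimic excess
paramagnetic Mn accumulation (Mn shortens T1, i.e. raises R1 — lesions are
additive and non-negative).

The smoothed noise field is renormalized by the L2 norm of the smoothing
kernel (periodic convolution) so the marginal per-voxel SD equals
``noise_sd`` exactly, whatever the FWHM; without this, smoothing would
silently shrink the variance the atlas RMSE is supposed to estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import CohortTableError, ConfigurationError, InvalidSpecError
from .volume_io import SubjectRecord, VolumeGrid, write_cohort_table, write_volume

__all__ = [
    "BACKGROUND",
    "GM",
    "WM",
    "GP",
    "PhantomSpec",
    "LesionSpec",
    "LesionPolicy",
    "SyntheticCohort",
    "generate_tissue_labels",
    "generate_subject",
    "generate_cohort",
    "wm_probability_map",
    "write_cohort",
]

# tissue label codes; every voxel carries exactly one
BACKGROUND, GM, WM, GP = 0, 1, 2, 3

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Geometry and generative parameters of a phantom cohort.

    Attributes
    ----------
    grid_shape, voxel_size:
        Sampling grid; all subjects share it.
    brain_axes_frac, wm_axes_frac:
        Semi-axes of the outer (GM) and inner (WM) ellipsoids as fractions of
        the grid extent per axis.
    gp_radius_mm, gp_offset_mm:
        Radius and center offset (mirrored in +-x) of the two GP spheres.
    baseline_r1:
        Mean R1 per tissue class in s^-1 at the reference age.
    age_coeffs:
        Global (beta_age, beta_age2) in s^-1/yr and s^-1/yr^2 applied inside
        the brain; arrays broadcastable to the grid may be substituted for a
        per-voxel model.
    ref_age:
        Age (whole years) at which tissue baselines apply.
    noise_sd:
        Marginal SD of the between-subject residual field, s^-1.
    smoothing_fwhm:
        Spatial correlation length (mm) of the residual field; 0 gives white
        noise.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_axes_frac: tuple[float, float, float] = (0.42, 0.45, 0.42)
    wm_axes_frac: tuple[float, float, float] = (0.30, 0.33, 0.30)
    gp_radius_mm: float = 6.0
    gp_offset_mm: tuple[float, float, float] = (12.0, -4.0, 0.0)
    baseline_r1: dict = field(
        default_factory=lambda: {"gm": 0.77, "wm": 1.07, "gp": 1.10}
    )
    age_coeffs: tuple = (0.002, -0.0002)
    ref_age: float = 39.0
    noise_sd: float = 0.15
    smoothing_fwhm: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise InvalidSpecError("grid_shape must be >= 16 along every axis")
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidSpecError("voxel_size must be positive")
        if self.gp_radius_mm <= 0:
            raise InvalidSpecError("gp_radius_mm must be > 0")
        if any(v <= 0 for v in self.baseline_r1.values()):
            raise InvalidSpecError("tissue baseline R1 values must be > 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.smoothing_fwhm < 0:
            raise InvalidSpecError("smoothing_fwhm must be >= 0")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        # center the world origin so phantoms look sane in viewers
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size
        return aff


@dataclass
class LesionSpec:
    """A focal additive R1 elevation: sphere of ``radius`` mm at a voxel center."""

    center: tuple[int, int, int]
    radius: float
    delta_r1: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidSpecError("lesion radius must be > 0")
        if self.delta_r1 < 0:
            raise InvalidSpecError("delta_r1 must be >= 0 (Mn only raises R1)")


@dataclass
class LesionPolicy:
    """How welder lesions are drawn: 0..max_lesions spheres in WM/GP."""

    max_lesions: int = 3
    radius_mm: tuple[float, float] = (3.0, 6.0)
    delta_r1: tuple[float, float] = (0.4, 1.2)

    def sample(self, rng: np.random.Generator, labels: VolumeGrid) -> list[LesionSpec]:
        candidates = np.argwhere((labels.data == WM) | (labels.data == GP))
        n = int(rng.integers(0, self.max_lesions + 1))
        lesions = []
        for _ in range(n):
            center = candidates[rng.integers(len(candidates))]
            lesions.append(
                LesionSpec(
                    center=tuple(int(c) for c in center),
                    radius=float(rng.uniform(*self.radius_mm)),
                    delta_r1=float(rng.uniform(*self.delta_r1)),
                )
            )
        return lesions


@dataclass
class SyntheticCohort:
    """Aligned phantom volumes plus metadata and the generating ground truth."""

    volumes: list[VolumeGrid]
    tissue_probability_maps: list[VolumeGrid]
    records: list[SubjectRecord]
    labels: VolumeGrid
    spec: PhantomSpec
    lesions: list[list[LesionSpec]]

    def controls(self) -> list[int]:
        return [i for i, r in enumerate(self.records) if r.group == "control"]

    def welders(self) -> list[int]:
        return [i for i, r in enumerate(self.records) if r.group == "welder"]


def _coords_mm(spec: PhantomSpec) -> list[np.ndarray]:
    """Open-grid voxel-center coordinates in mm, origin at the grid center."""
    axes = []
    for n, v in zip(spec.grid_shape, spec.voxel_size):
        axes.append((np.arange(n) - (n - 1) / 2.0) * v)
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def generate_tissue_labels(spec: PhantomSpec) -> VolumeGrid:
    """Deterministic label volume of nested ellipsoids.

    Outer ellipsoid = GM shell, inner = WM core, two mirrored spheres = GP.
    """
    spec.validate()
    x, y, z = _coords_mm(spec)
    extent = [n * v for n, v in zip(spec.grid_shape, spec.voxel_size)]

    def ellipsoid(axes_frac):
        a, b, c = [f * e for f, e in zip(axes_frac, extent)]
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[ellipsoid(spec.brain_axes_frac)] = GM
    labels[ellipsoid(spec.wm_axes_frac)] = WM
    ox, oy, oz = spec.gp_offset_mm
    for sx in (+1.0, -1.0):
        gp = (x - sx * ox) ** 2 + (y - oy) ** 2 + (z - oz) ** 2 <= spec.gp_radius_mm**2
        labels[gp & (labels != BACKGROUND)] = GP
    if not np.any(labels == WM):
        raise InvalidSpecError("geometry leaves zero WM voxels")
    return VolumeGrid(labels, spec.affine)


def _smoothing_sigma_vox(spec: PhantomSpec) -> list[float]:
    return [
        spec.smoothing_fwhm * _FWHM_TO_SIGMA / v for v in spec.voxel_size
    ]


def _kernel_l2_norm(spec: PhantomSpec) -> float:
    """L2 norm of the periodic smoothing kernel (variance shrink factor)."""
    impulse = np.zeros(spec.grid_shape)
    impulse[tuple(n // 2 for n in spec.grid_shape)] = 1.0
    response = gaussian_filter(impulse, _smoothing_sigma_vox(spec), mode="wrap")
    return float(np.sqrt(np.sum(response**2)))


def _noise_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(spec.grid_shape)
    if spec.smoothing_fwhm > 0:
        smooth = gaussian_filter(white, _smoothing_sigma_vox(spec), mode="wrap")
        white = smooth / _kernel_l2_norm(spec)
    return spec.noise_sd * white


def _lesion_mask(spec: PhantomSpec, lesion: LesionSpec) -> np.ndarray:
    x, y, z = _coords_mm(spec)
    cx = (lesion.center[0] - (spec.grid_shape[0] - 1) / 2.0) * spec.voxel_size[0]
    cy = (lesion.center[1] - (spec.grid_shape[1] - 1) / 2.0) * spec.voxel_size[1]
    cz = (lesion.center[2] - (spec.grid_shape[2] - 1) / 2.0) * spec.voxel_size[2]
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= lesion.radius**2


def generate_subject(
    spec: PhantomSpec,
    labels: VolumeGrid,
    age: int,
    lesions: Sequence[LesionSpec] = (),
    subject_seed: int = 0,
) -> VolumeGrid:
    """One subject's R1 map: tissue baseline + quadratic age term + smooth
    Gaussian residual + additive lesions. Background stays 0."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    spec.validate()
    lab = labels.data
    brain = lab != BACKGROUND
    r1 = np.zeros(spec.grid_shape, dtype=np.float64)
    r1[lab == GM] = spec.baseline_r1["gm"]
    r1[lab == WM] = spec.baseline_r1["wm"]
    r1[lab == GP] = spec.baseline_r1["gp"]

    a = float(age) - spec.ref_age
    beta_age, beta_age2 = spec.age_coeffs
    age_term = np.broadcast_to(
        np.asarray(beta_age) * a + np.asarray(beta_age2) * a * a, spec.grid_shape
    )
    r1[brain] += age_term[brain]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(subject_seed)
        r1[brain] += _noise_field(spec, rng)[brain]

    for lesion in lesions:
        r1[_lesion_mask(spec, lesion) & brain] += lesion.delta_r1

    # Mn physiology: R1 stays positive in tissue (floor is ~7 sigma out at defaults)
    r1[brain] = np.maximum(r1[brain], 1e-3)
    return VolumeGrid(r1, spec.affine)


def wm_probability_map(labels: VolumeGrid) -> VolumeGrid:
    """WM probability: 1 inside WM+GP with a softly blurred boundary, in [0,1].

    Mirrors segmentation output closely enough that mean-and-threshold mask
    building behaves as it would on real probability maps; the GP is folded
    into the WM probability so a 50% threshold includes it, as a WM-biased
    partial-volume boundary does in practice.
    """
    ind = ((labels.data == WM) | (labels.data == GP)).astype(np.float64)
    prob = gaussian_filter(ind, sigma=1.0)
    return labels.like(np.clip(prob, 0.0, 1.0))


def _sample_exposure(rng: np.random.Generator, group: str) -> dict:
    # ranges follow occupational cohorts: welder air Mn ~0.05-0.48 mg/m^3,
    # CEI_3M up to ~0.18, CEI_Life up to ~4.8 mg/m^3*yr; controls near zero
    if group == "welder":
        return {
            "air_mn": round(float(rng.uniform(0.05, 0.48)), 3),
            "cei_3m": round(float(rng.uniform(0.006, 0.18)), 3),
            "cei_life": round(float(rng.uniform(0.03, 4.8)), 3),
        }
    return {
        "air_mn": round(float(rng.uniform(0.0, 0.027)), 3),
        "cei_3m": round(float(rng.uniform(0.0, 0.006)), 4),
        "cei_life": round(float(rng.uniform(0.003, 0.4)), 3),
    }


def generate_cohort(
    spec: PhantomSpec,
    n_controls: int = 25,
    n_welders: int = 10,
    age_range: tuple[int, int] = (20, 61),
    lesion_policy: LesionPolicy | None = None,
) -> SyntheticCohort:
    """Generate an aligned phantom cohort.

    Controls are lesion-free; welders receive lesions per ``lesion_policy``.
    Ages are whole years drawn uniformly over ``age_range`` (inclusive). All
    randomness derives from ``spec.seed``.
    """
    if n_controls < 4:
        raise CohortTableError(
            f"need at least 4 controls to fit the atlas, got {n_controls}"
        )
    if n_welders < 0:
        raise ConfigurationError("n_welders must be >= 0")
    spec.validate()
    if lesion_policy is None:
        lesion_policy = LesionPolicy()
    labels = generate_tissue_labels(spec)
    prob = wm_probability_map(labels)
    rng = np.random.default_rng(spec.seed)

    volumes, records, lesions_per_subject, prob_maps = [], [], [], []
    groups = ["control"] * n_controls + ["welder"] * n_welders
    n_c = n_w = 0
    for group in groups:
        if group == "control":
            n_c += 1
            sid = f"C{n_c:02d}"
        else:
            n_w += 1
            sid = f"W{n_w:02d}"
        age = int(rng.integers(age_range[0], age_range[1] + 1))
        subject_seed = int(rng.integers(0, 2**31 - 1))
        lesions = lesion_policy.sample(rng, labels) if group == "welder" else []
        volumes.append(generate_subject(spec, labels, age, lesions, subject_seed))
        prob_maps.append(prob)
        records.append(SubjectRecord(subject_id=sid, age=age, group=group, **_sample_exposure(rng, group)))
        lesions_per_subject.append(lesions)
    return SyntheticCohort(
        volumes=volumes,
        tissue_probability_maps=prob_maps,
        records=records,
        labels=labels,
        spec=spec,
        lesions=lesions_per_subject,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write NIfTI volumes, a cohort CSV and a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for record, vol, prob in zip(
        cohort.records, cohort.volumes, cohort.tissue_probability_maps
    ):
        write_volume(vol, outdir / f"{record.subject_id}_r1.nii")
        write_volume(prob, outdir / f"{record.subject_id}_wmprob.nii")
    write_volume(cohort.labels, outdir / "tissue_labels.nii", dtype=np.int16)
    write_cohort_table(cohort.records, outdir / "cohort.csv")
    truth = {
        "spec": asdict(cohort.spec),
        "lesions": [
            [asdict(lesion) for lesion in lesions] for lesions in cohort.lesions
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
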