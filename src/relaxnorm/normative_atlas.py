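"""Normative R1 atlas: WM analysis mask and voxel-wise quadratic age model.

The atlas models healthy-cohort R1 at every voxel r as

    E{R1}(r) = beta0(r) + beta_age(r) * a + beta_age2(r) * a^2,
    a = age - ref_age (whole years, centered at the cohort mean age),

fit by ordinary least squares independently per voxel. The quadratic term
captures the inverse-U trajectory of R1 over the adult lifespan. The RMSE
map — the residual SD of the fit — is the denominator of single-subject
z-scores, so voxels with a degenerate fit (zero residual variance) are
removed from the analysis mask rather than allowed to produce infinite z.

The analysis mask is built by averaging the cohort's WM probability maps and
keeping voxels whose mean strictly exceeds the threshold (default 50%); with
WM-biased probability maps this includes the globus pallidus but not cortex.

The cohort studied here is male-only, so no sex covariate is fit; additional
covariate columns can be passed for cohorts that need them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateMaskError,
    DesignError,
)
from .volume_io import VolumeGrid, assert_shared_grid, read_volume, write_volume

__all__ = [
    "AnalysisMask",
    "NormativeAtlas",
    "build_wm_mask",
    "fit_atlas",
    "predict",
    "save_atlas",
    "load_atlas",
]


@dataclass
class AnalysisMask:
    """Binary analysis mask plus the rule that produced it."""

    mask: VolumeGrid
    threshold: float = 0.5
    n_subjects_averaged: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("mask threshold must lie in (0, 1)")

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.data)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask.data))


@dataclass
class NormativeAtlas:
    """Per-voxel coefficient and RMSE maps of the age model."""

    beta0: VolumeGrid
    beta_age: VolumeGrid
    beta_age2: VolumeGrid
    rmse: VolumeGrid
    ref_age: float
    mask: AnalysisMask
    n_subjects: int
    rmse_denominator: str = "df"  # "df" -> n-3, "n" -> n


def build_wm_mask(
    wm_probability_maps: Sequence[VolumeGrid], threshold: float = 0.5
) -> AnalysisMask:
    """Mean WM probability strictly above ``threshold`` defines the mask."""
    maps = list(wm_probability_maps)
    if not maps:
        raise ConfigurationError("need at least one WM probability map")
    assert_shared_grid(maps)
    stack = np.stack([m.data for m in maps])
    if stack.min() < 0.0 or stack.max() > 1.0:
        raise ConfigurationError("probability maps must lie in [0, 1]")
    mean = stack.mean(axis=0)
    mask = mean > threshold  # strict: exactly-at-threshold voxels are excluded
    if not mask.any():
        raise DegenerateMaskError(f"no voxel has mean WM probability > {threshold}")
    return AnalysisMask(
        mask=maps[0].like(mask), threshold=threshold, n_subjects_averaged=len(maps)
    )


def _design_matrix(ages: np.ndarray, ref_age: float) -> np.ndarray:
    a = ages - ref_age
    return np.column_stack([np.ones_like(a), a, a * a])


def fit_atlas(
    cohort_volumes: Sequence[VolumeGrid],
    ages: Sequence[int],
    mask: AnalysisMask,
    rmse_denominator: str = "df",
    extra_covariates: np.ndarray | None = None,
) -> NormativeAtlas:
    """Fit the voxel-wise age model over a control cohort.

    Requires >= 4 subjects and >= 3 distinct ages (the quadratic design is
    rank-deficient otherwise). Voxels where any subject is non-finite, or
    where the fit is degenerate (zero residual variance), are dropped from
    the analysis mask.
    """
    volumes = list(cohort_volumes)
    ages_arr = np.asarray(ages, dtype=float)
    if len(volumes) != len(ages_arr):
        raise ConfigurationError(
            f"{len(volumes)} volumes but {len(ages_arr)} ages"
        )
    if len(volumes) < 4:
        raise ConfigurationError("atlas fit needs at least 4 subjects")
    if len(np.unique(ages_arr)) < 3:
        raise DesignError("need >= 3 distinct ages for the quadratic model")
    if rmse_denominator not in ("df", "n"):
        raise ConfigurationError("rmse_denominator must be 'df' or 'n'")
    assert_shared_grid(list(volumes) + [mask.mask])

    n = len(volumes)
    ref_age = float(ages_arr.mean())
    X = _design_matrix(ages_arr, ref_age)
    if extra_covariates is not None:
        X = np.column_stack([X, np.asarray(extra_covariates, dtype=float)])
    p = X.shape[1]
    if n <= p and rmse_denominator == "df":
        raise ConfigurationError(f"need > {p} subjects for residual df")

    idx = mask.indices
    Y = np.stack([v.data.reshape(-1)[idx] for v in volumes])  # n x nvox
    finite = np.isfinite(Y).all(axis=0)

    beta = np.full((p, idx.size), np.nan)
    rmse_vals = np.full(idx.size, np.nan)
    if finite.any():
        Yf = Y[:, finite]
        coef, _, rank, _ = np.linalg.lstsq(X, Yf, rcond=None)
        if rank < p:
            raise DesignError("design matrix is rank-deficient")
        resid = Yf - X @ coef
        ssr = np.einsum("ij,ij->j", resid, resid)
        denom = (n - p) if rmse_denominator == "df" else n
        beta[:, finite] = coef
        rmse_vals[finite] = np.sqrt(np.maximum(ssr, 0.0) / denom)

    # Degenerate voxels (zero residual SD, i.e. a perfect fit) keep their
    # coefficients in the maps but are excluded from the analysis mask: the
    # z-score divides by RMSE. Non-finite voxels are excluded outright.
    scale = np.nanmax(np.abs(Y), initial=1.0)
    good = finite & (rmse_vals > 1e-12 * max(scale, 1.0))

    shape = mask.mask.shape
    grid = mask.mask

    def to_volume(values: np.ndarray) -> VolumeGrid:
        out = np.full(np.prod(shape), np.nan)
        out[idx] = values
        return grid.like(out.reshape(shape))

    new_mask_flat = np.zeros(np.prod(shape), dtype=bool)
    new_mask_flat[idx[good]] = True
    fitted_mask = AnalysisMask(
        mask=grid.like(new_mask_flat.reshape(shape)),
        threshold=mask.threshold,
        n_subjects_averaged=mask.n_subjects_averaged,
    )
    return NormativeAtlas(
        beta0=to_volume(beta[0]),
        beta_age=to_volume(beta[1]),
        beta_age2=to_volume(beta[2]),
        rmse=to_volume(rmse_vals),
        ref_age=ref_age,
        mask=fitted_mask,
        n_subjects=n,
        rmse_denominator=rmse_denominator,
    )


def predict(atlas: NormativeAtlas, age: float) -> VolumeGrid:
    """Expected R1 at ``age``: beta0 + beta_age*a + beta_age2*a^2, NaN outside mask."""
    a = float(age) - atlas.ref_age
    if abs(a) > 60.0:
        warnings.warn(
            f"age {age} is far from the reference age {atlas.ref_age:.1f}; "
            "extrapolating the quadratic model",
            stacklevel=2,
        )
    if a == 0.0:
        expected = atlas.beta0.data.copy()
    else:
        expected = atlas.beta0.data + atlas.beta_age.data * a + atlas.beta_age2.data * a * a
    expected = np.where(atlas.mask.mask.data, expected, np.nan)
    return atlas.beta0.like(expected)


def save_atlas(atlas: NormativeAtlas, outdir: str | Path) -> Path:
    """Persist the atlas as four NIfTI maps + mask + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.beta0, outdir / "beta0.nii")
    write_volume(atlas.beta_age, outdir / "beta_age.nii")
    write_volume(atlas.beta_age2, outdir / "beta_age2.nii")
    write_volume(atlas.rmse, outdir / "rmse.nii")
    write_volume(
        atlas.mask.mask.like(atlas.mask.mask.data.astype(np.uint8)),
        outdir / "mask.nii",
        dtype=np.uint8,
    )
    meta = {
        "ref_age": atlas.ref_age,
        "n_subjects": atlas.n_subjects,
        "mask_threshold": atlas.mask.threshold,
        "mask_n_subjects_averaged": atlas.mask.n_subjects_averaged,
        "rmse_denominator": atlas.rmse_denominator,
    }
    (outdir / "atlas.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_atlas(indir: str | Path) -> NormativeAtlas:
    indir = Path(indir)
    meta = json.loads((indir / "atlas.json").read_text())
    mask_vol = read_volume(indir / "mask.nii")
    mask = AnalysisMask(
        mask=mask_vol.like(mask_vol.data > 0),
        threshold=meta["mask_threshold"],
        n_subjects_averaged=meta["mask_n_subjects_averaged"],
    )
    return NormativeAtlas(
        beta0=read_volume(indir / "beta0.nii"),
        beta_age=read_volume(indir / "beta_age.nii"),
        beta_age2=read_volume(indir / "beta_age2.nii"),
        rmse=read_volume(indir / "rmse.nii"),
        ref_age=meta["ref_age"],
        mask=mask,
        n_subjects=meta["n_subjects"],
        rmse_denominator=meta["rmse_denominator"],
    )
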