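"""Two-point variable-flip-angle (VFA) R1 fitting.

The spoiled-gradient-echo steady-state signal at flip angle ``a`` is

    S(a) = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR * R1)

which linearizes as S/sin(a) = E1 * S/tan(a) + M0 * (1 - E1) (DESPOT1).
With exactly two flip angles the slope E1 — and hence R1 = -ln(E1)/TR — is
determined in closed form per voxel. Nominal flip angles are trusted: B1
(transmit-field) correction is an acquisition-side concern outside this
package, and synthetic phantoms carry no B1 inhomogeneity.

Voxels whose slope falls outside (0, 1) have no physical R1 under the model
(e.g. zero signal, pure noise) and are marked NaN; downstream stages treat
NaN as outside the analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FitFailureError
from .volume_io import VolumeGrid, assert_shared_grid

__all__ = ["VfaAcquisition", "forward_vfa_signal", "fit_vfa_r1"]


@dataclass
class VfaAcquisition:
    """Two SPGR magnitude volumes acquired at distinct flip angles."""

    signals: tuple[VolumeGrid, VolumeGrid]
    flip_angles_deg: tuple[float, float] = (3.0, 17.0)
    tr_ms: float = 6.36

    def __post_init__(self) -> None:
        if len(self.signals) != 2 or len(self.flip_angles_deg) != 2:
            raise ConfigurationError("exactly two flip angles / signal volumes required")
        a1, a2 = self.flip_angles_deg
        if a1 == a2:
            raise ConfigurationError("flip angles must be distinct")
        if not all(0.0 < a < 90.0 for a in (a1, a2)):
            raise ConfigurationError("flip angles must lie in (0, 90) degrees")
        if self.tr_ms <= 0:
            raise ConfigurationError("TR must be positive")
        assert_shared_grid(self.signals)


def forward_vfa_signal(
    r1: np.ndarray | float,
    m0: np.ndarray | float,
    flip_deg: float,
    tr_ms: float = 6.36,
) -> np.ndarray:
    """Noiseless SPGR steady-state signal for given R1 (s^-1) and M0."""
    alpha = np.deg2rad(flip_deg)
    e1 = np.exp(-(tr_ms / 1000.0) * np.asarray(r1, dtype=float))
    return np.asarray(m0, dtype=float) * np.sin(alpha) * (1.0 - e1) / (
        1.0 - e1 * np.cos(alpha)
    )


def fit_vfa_r1(acq: VfaAcquisition, mask: VolumeGrid | None = None) -> VolumeGrid:
    """Closed-form two-point DESPOT1 fit; returns R1 in s^-1, NaN where invalid.

    Raises :class:`FitFailureError` if no in-mask voxel yields a physical fit.
    """
    s1, s2 = (np.asarray(v.data, dtype=float) for v in acq.signals)
    grid = acq.signals[0]
    if mask is not None:
        assert_shared_grid([grid, mask])
        inmask = mask.data > 0
    else:
        inmask = np.ones(grid.shape, dtype=bool)

    a1, a2 = np.deg2rad(np.asarray(acq.flip_angles_deg, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        y1, y2 = s1 / np.sin(a1), s2 / np.sin(a2)
        x1, x2 = s1 / np.tan(a1), s2 / np.tan(a2)
        slope = (y2 - y1) / (x2 - x1)
        valid = inmask & np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
        r1 = np.where(valid, -np.log(np.where(valid, slope, 0.5)) / (acq.tr_ms / 1000.0), np.nan)
    if inmask.any() and not valid.any():
        raise FitFailureError("no voxel produced a physical E1 in (0, 1)")
    return grid.like(r1)
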