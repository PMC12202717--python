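"""Pointwise SAR, smoothing, outlier removal, correction, and normalization.

The local SAR for time-harmonic fields with peak complex amplitudes is

    SAR = sigma * (|Ex|^2 + |Ey|^2 + |Ez|^2) / (2 * rho)      [W/kg]

The processing order is fixed and logged: pointwise SAR -> Gaussian smooth
(sigma 0.4 voxels, mask-renormalised so background never leaks in) ->
outlier removal (values above mean + 9 SD become undefined) -> tissue-wise
multiplicative correction.  Outliers are excluded, not clamped, so they also
drop out of every downstream statistic.

Undefined voxels are NaN throughout; background is whatever the label map
says it is and is never touched by correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .efield import EFieldMap
from .physics_config import CorrectionFactorTable, PhysicsConfig
from .volgrid import TissueLabelMap, VolumeGrid

logger = logging.getLogger("imsar")

__all__ = [
    "SARResult",
    "pointwise_sar",
    "gaussian_smooth",
    "remove_outliers",
    "apply_correction",
    "normalize_for_comparison",
]


@dataclass
class SARResult:
    """Paired uncorrected/corrected SAR and 10-g SAR maps plus provenance."""

    sar_uncorrected: VolumeGrid
    sar_corrected: VolumeGrid
    sar10g_uncorrected: VolumeGrid | None = None
    sar10g_corrected: VolumeGrid | None = None
    factors_applied: CorrectionFactorTable | None = None
    provenance: list[dict] = field(default_factory=list)

    def log_step(self, name: str, **params) -> None:
        self.provenance.append({"step": name, **params})


def pointwise_sar(E: EFieldMap, sigma: VolumeGrid, cfg: PhysicsConfig) -> VolumeGrid:
    """SAR = sigma |E|^2 / (2 rho), treating stored amplitudes as peak values."""
    if not E.ex.same_geometry(sigma):
        raise ValueError("E-field and sigma must share geometry")
    sar = np.asarray(sigma.data, dtype=float) * E.magnitude_squared() / (2.0 * cfg.rho)
    return sigma.with_data(sar, units="W/kg")


def gaussian_smooth(
    sar: VolumeGrid, sigma_g: float = 0.4, mask: np.ndarray | None = None
) -> VolumeGrid:
    """Separable Gaussian smoothing over the foreground, mask-renormalised.

    sigma_g is in voxel units.  Normalised convolution: the volume (with
    undefined/background voxels zero-filled) and the defined-voxel indicator
    are both smoothed and the ratio taken, so background never bleeds into
    the foreground.  sigma_g = 0 is the identity.
    """
    if sigma_g < 0:
        raise ValueError("sigma_g must be >= 0")
    data = np.asarray(sar.data, dtype=float)
    defined = np.isfinite(data)
    if mask is not None:
        defined &= mask
    if sigma_g == 0:
        out = np.where(defined, data, np.nan)
        return sar.with_data(out)
    num = ndimage.gaussian_filter(np.where(defined, data, 0.0), sigma_g)
    den = ndimage.gaussian_filter(defined.astype(float), sigma_g)
    out = np.full(sar.shape, np.nan)
    ok = defined & (den > 0)
    out[ok] = num[ok] / den[ok]
    return sar.with_data(out)


def remove_outliers(
    v: VolumeGrid, k: float = 9.0, mask: np.ndarray | None = None
) -> tuple[VolumeGrid, int]:
    """Set voxels above mean + k*SD to undefined (NaN); single pass.

    Mean and SD are computed once over the defined (finite, in-mask) voxels
    and not iterated.  A uniform map (SD 0) removes nothing because the
    threshold equals the common value and the comparison is strict.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    data = np.asarray(v.data, dtype=float)
    defined = np.isfinite(data)
    if mask is not None:
        defined &= mask
    if not defined.any():
        return v.with_data(data.copy()), 0
    vals = data[defined]
    thr = float(vals.mean()) + k * float(vals.std(ddof=0))
    kill = defined & (data > thr)
    out = data.copy()
    out[kill] = np.nan
    n = int(kill.sum())
    logger.info("outlier removal: threshold %.6g, removed %d voxels", thr, n)
    return v.with_data(out), n


def apply_correction(
    sar: VolumeGrid,
    labels: TissueLabelMap,
    table: CorrectionFactorTable,
    which: str = "sar",
) -> VolumeGrid:
    """Voxelwise multiplication by the tissue's correction factor.

    ``which`` selects the factor table ("sar" or "sar10g").  Background is
    untouched; a foreground tissue without a factor raises, naming it.
    """
    if which not in ("sar", "sar10g"):
        raise ValueError(f"which must be 'sar' or 'sar10g', got {which!r}")
    if sar.shape != labels.shape:
        raise ValueError("SAR map and labels must share geometry")
    factors = table.sar_factor if which == "sar" else table.sar10g_factor
    out = np.asarray(sar.data, dtype=float).copy()
    for code in labels.tissue_codes():
        if code not in factors:
            name = labels.code_table.get(code, str(code))
            raise ValueError(f"no {which} correction factor for tissue {name!r} (code {code})")
        sel = labels.labels == code
        out[sel] = out[sel] * factors[code]
    return sar.with_data(out)


def normalize_for_comparison(v: VolumeGrid, k: float = 9.0) -> VolumeGrid:
    """Z-score outlier removal (k SD) then division by the surviving maximum.

    Output lies in [0, 1] over the defined voxels, the surviving maximum
    mapping to exactly 1.
    """
    cleaned, _ = remove_outliers(v, k=k)
    data = np.asarray(cleaned.data, dtype=float)
    defined = np.isfinite(data)
    if not defined.any():
        raise ValueError("no defined voxels to normalize")
    peak = float(np.nanmax(data))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero map")
    return cleaned.with_data(data / peak, units="1")
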