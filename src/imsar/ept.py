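"""Phase-based Helmholtz-EPT conductivity reconstruction.

For quadrature transmit/receive at 3 T the measured transceive phase of a
bSSFP-like sequence approximates twice the transmit (B1+) phase, and within a
locally homogeneous region the Helmholtz relation reduces to

    sigma = laplacian(phi_tr) / (2 * mu0 * omega)

The Laplacian is evaluated with a 3D Savitzky-Golay filter: at every
foreground voxel a degree-2 polynomial is fit to the phase over a local
footprint by weighted least squares, and the Laplacian is read off the
quadratic coefficients.  Anatomical adaptation down-weights footprint voxels
whose reference-image intensity differs from the centre voxel, so the fit
does not differentiate across tissue boundaries.

The same engine provides first derivatives (gradients) for the E-field stage.

Noisy, rank-deficient, or isolated voxels are marked unreconstructable (NaN)
rather than raising; NaN propagates through all downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .physics_config import PhysicsConfig
from .volgrid import TissueLabelMap, VolumeGrid

logger = logging.getLogger("imsar")

__all__ = [
    "SGKernel",
    "sg_fit_weights",
    "sg_laplacian",
    "sg_gradient_fields",
    "conductivity_from_phase",
    "ept_postprocess",
    "piecewise_mean_conductivity",
]

# Monomial order of the degree-2 fit (voxel-offset units):
# 1, x, y, z, x^2, y^2, z^2, xy, xz, yz
N_MONOMIALS = 10

#: effective weight below which a footprint voxel does not count toward rank
_WEIGHT_EPS = 1e-6
#: target number of gathered footprint elements per batched chunk; the
#: per-chunk centre count adapts to the footprint size to bound memory
_CHUNK_ELEMS = 4_000_000


@dataclass
class SGKernel:
    """Shape, size, degree and adaptation of a Savitzky-Golay neighborhood.

    ``size`` follows the half-extent convention: a cuboid of size 5 is the
    5x5x5 symmetric footprint (half-extent ``5 // 2 = 2``); a cube of size 10
    is the symmetric 11x11x11 footprint (half-extent 5); an ellipsoid of size
    4 has semi-axes of 4 voxels (9 voxels full width per axis, masked to the
    ellipsoid).

    ``adaptation`` is an optional ``(reference VolumeGrid, weight w)`` pair;
    see :func:`sg_fit_weights`.
    """

    shape: str = "cuboid"  # cuboid | cube | ellipsoid
    size: int = 5
    degree: int = 2
    adaptation: tuple[VolumeGrid, float] | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("cuboid", "cube", "ellipsoid"):
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        if self.size < 1:
            raise ValueError("kernel size must be >= 1")
        if self.degree != 2:
            # degree 2 is the minimum exposing a Laplacian and the degree the
            # whole pipeline is built on
            raise ValueError("only degree-2 kernels are supported")
        if self.offsets().shape[0] <= N_MONOMIALS:
            raise ValueError(
                f"kernel footprint of {self.offsets().shape[0]} voxels cannot "
                f"determine {N_MONOMIALS} polynomial coefficients"
            )

    @property
    def half_extent(self) -> int:
        if self.shape == "ellipsoid":
            return self.size
        return self.size // 2

    def offsets(self) -> np.ndarray:
        """(P, 3) integer voxel offsets of the footprint."""
        h = self.half_extent
        rng = np.arange(-h, h + 1)
        dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
        offs = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
        if self.shape == "ellipsoid":
            r2 = (offs.astype(float) / max(h, 1)) ** 2
            offs = offs[r2.sum(axis=1) <= 1.0 + 1e-12]
        return offs


def sg_fit_weights(
    center_ref: np.ndarray,
    footprint_ref: np.ndarray,
    footprint_foreground: np.ndarray,
    w: float,
    ref_range: float,
) -> np.ndarray:
    """Anatomical adaptation weights for one or many kernel footprints.

    Voxel j of a footprint centred on a voxel with reference intensity R0
    weighs ``exp(-(R_j - R0)^2 / (2 * (w * dR)^2))`` with ``dR`` the reference
    range over the foreground; background voxels always weigh 0.  A uniform
    reference (dR == 0) or ``w -> inf`` gives unit weights in-footprint.

    Parameters are broadcastable: ``center_ref`` of shape (...,) against
    ``footprint_ref`` / ``footprint_foreground`` of shape (..., P).
    """
    fg = np.asarray(footprint_foreground, dtype=bool)
    if ref_range <= 0 or not np.isfinite(w) or w <= 0:
        weights = np.ones_like(np.asarray(footprint_ref, dtype=float))
    else:
        diff = np.asarray(footprint_ref, dtype=float) - np.asarray(center_ref, dtype=float)[..., None]
        scale = 2.0 * (w * ref_range) ** 2
        weights = np.exp(-(diff**2) / scale)
    weights = np.where(fg, weights, 0.0)
    return weights


# ---------------------------------------------------------------------------
# Shared weighted-least-squares engine
# ---------------------------------------------------------------------------

def _design_matrix(offsets: np.ndarray) -> np.ndarray:
    """(P, 10) monomial design matrix in voxel-offset units."""
    x, y, z = offsets[:, 0].astype(float), offsets[:, 1].astype(float), offsets[:, 2].astype(float)
    return np.stack(
        [np.ones_like(x), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z], axis=1
    )


def _iter_footprints(
    fields: Sequence[np.ndarray],
    mask: np.ndarray,
    kernel: SGKernel,
) -> Iterator[tuple[np.ndarray, np.ndarray, list[np.ndarray]]]:
    """Yield (centre indices (n,3), weights (n,P), field values [(n,P)...]).

    Weights combine the foreground mask, finiteness of every field, and the
    kernel's anatomical adaptation.  Footprints are implicitly clipped to the
    volume (out-of-volume voxels weigh 0).
    """
    offs = kernel.offsets()
    h = kernel.half_extent
    pad = ((h, h), (h, h), (h, h))

    finite = np.ones_like(mask, dtype=bool)
    padded_fields = []
    for f in fields:
        finite &= np.isfinite(f) if not np.iscomplexobj(f) else np.isfinite(f.real) & np.isfinite(f.imag)
        padded_fields.append(np.pad(np.nan_to_num(f, nan=0.0), pad))
    valid = mask & finite
    padded_valid = np.pad(valid, pad)

    ref = None
    ref_range = 0.0
    w = 0.0
    if kernel.adaptation is not None:
        ref_grid, w = kernel.adaptation
        ref = np.asarray(ref_grid.data, dtype=float)
        if ref.shape != mask.shape:
            raise ValueError("adaptation reference geometry does not match the volume")
        in_fg = ref[mask]
        ref_range = float(np.nanmax(in_fg) - np.nanmin(in_fg)) if in_fg.size else 0.0
        padded_ref = np.pad(np.nan_to_num(ref, nan=0.0), pad)

    centers = np.argwhere(mask)
    padded_shape = padded_valid.shape
    chunk = max(512, _CHUNK_ELEMS // offs.shape[0])
    for start in range(0, centers.shape[0], chunk):
        c = centers[start : start + chunk]
        nb = c[:, None, :] + offs[None, :, :] + h  # indices into padded arrays
        flat = np.ravel_multi_index((nb[..., 0], nb[..., 1], nb[..., 2]), padded_shape)
        fg = padded_valid.ravel()[flat]
        if ref is not None:
            r = padded_ref.ravel()[flat]
            r0 = ref[c[:, 0], c[:, 1], c[:, 2]]
            weights = sg_fit_weights(r0, r, fg, w, ref_range)
        else:
            weights = fg.astype(float)
        values = [pf.ravel()[flat] for pf in padded_fields]
        yield c, weights, values


def _sg_polyfit(
    fields: Sequence[np.ndarray],
    mask: np.ndarray,
    kernel: SGKernel,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched degree-2 WLS fit at every mask voxel.

    Returns ``coeffs`` of shape mask.shape + (10, F) (NaN where the fit is
    unreconstructable) and the boolean validity mask.
    """
    offs = kernel.offsets()
    Phi = _design_matrix(offs)  # (P, 10)
    outer = (Phi[:, :, None] * Phi[:, None, :]).reshape(Phi.shape[0], -1)  # (P, 100)

    any_complex = any(np.iscomplexobj(f) for f in fields)
    dtype = np.complex128 if any_complex else np.float64
    F = len(fields)
    coeffs = np.full(mask.shape + (N_MONOMIALS, F), np.nan, dtype=dtype)
    valid = np.zeros(mask.shape, dtype=bool)

    for c, W, values in _iter_footprints(fields, mask, kernel):
        n = c.shape[0]
        count = (W > _WEIGHT_EPS).sum(axis=1)
        ok = count > N_MONOMIALS
        A = (W @ outer).reshape(n, N_MONOMIALS, N_MONOMIALS)
        B = np.empty((n, N_MONOMIALS, F), dtype=dtype)
        for j, Y in enumerate(values):
            B[:, :, j] = (W * Y) @ Phi
        sol = np.full((n, N_MONOMIALS, F), np.nan, dtype=dtype)
        if np.any(ok):
            try:
                sol[ok] = np.linalg.solve(A[ok], B[ok])
            except np.linalg.LinAlgError:
                # rare: some footprint is rank-deficient despite the voxel
                # count check; fall back to a pseudo-inverse for the chunk
                sol[ok] = np.linalg.pinv(A[ok]) @ B[ok]
        bad = ~np.all(np.isfinite(sol.reshape(n, -1)), axis=1)
        ok &= ~bad
        ix, iy, iz = c[:, 0], c[:, 1], c[:, 2]
        coeffs[ix, iy, iz] = sol
        valid[ix, iy, iz] = ok
    coeffs[~valid] = np.nan
    return coeffs, valid


def _spacing_m(v: VolumeGrid) -> np.ndarray:
    return np.asarray(v.spacing, dtype=float) * 1e-3


def sg_laplacian(
    phase: VolumeGrid, kernel: SGKernel, mask: np.ndarray | None = None
) -> VolumeGrid:
    """Savitzky-Golay Laplacian of a phase volume, rad/m^2.

    At each foreground voxel a weighted degree-2 polynomial is fit over the
    kernel footprint in physical coordinates; the output is
    ``2 * (a_xx + a_yy + a_zz)`` from the fitted quadratic coefficients.
    Unreconstructable voxels (insufficient support) are NaN.
    """
    if mask is None:
        mask = np.isfinite(phase.data)
    coeffs, valid = _sg_polyfit([np.asarray(phase.data, dtype=float)], mask, kernel)
    h = _spacing_m(phase)
    lap = 2.0 * (
        coeffs[..., 4, 0] / h[0] ** 2
        + coeffs[..., 5, 0] / h[1] ** 2
        + coeffs[..., 6, 0] / h[2] ** 2
    )
    lap[~valid] = np.nan
    return phase.with_data(lap, units="rad/m^2")


def sg_gradient_fields(
    field: VolumeGrid, kernel: SGKernel, mask: np.ndarray | None = None
) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid]:
    """Per-axis first derivatives of a (possibly complex) volume, 1/m scaled.

    Real and imaginary parts share the same adaptation weights because the
    weights depend only on the real-valued anatomical reference.
    """
    data = np.asarray(field.data)
    if mask is None:
        if np.iscomplexobj(data):
            mask = np.isfinite(data.real) & np.isfinite(data.imag)
        else:
            mask = np.isfinite(data)
    coeffs, valid = _sg_polyfit([data], mask, kernel)
    h = _spacing_m(field)
    out = []
    for axis in range(3):
        g = coeffs[..., 1 + axis, 0] / h[axis]
        g[~valid] = np.nan
        out.append(field.with_data(g, units=f"{field.units}/m"))
    return tuple(out)


# ---------------------------------------------------------------------------
# Conductivity reconstruction
# ---------------------------------------------------------------------------

def conductivity_from_phase(
    phase: VolumeGrid,
    kernel: SGKernel,
    cfg: PhysicsConfig,
    mask: np.ndarray | None = None,
) -> VolumeGrid:
    """Phase-based Helmholtz-EPT: sigma = laplacian(phi_tr) / (2 mu0 omega).

    ``phase`` is the transceive phase in rad.  Negative values are retained
    (not clipped) so that downstream per-tissue statistics can handle them
    explicitly; unreconstructable voxels are NaN.
    """
    lap = sg_laplacian(phase, kernel, mask=mask)
    sigma = lap.data / (2.0 * cfg.mu0 * cfg.omega)
    return phase.with_data(sigma, units="S/m")


def ept_postprocess(
    sigma: VolumeGrid,
    reference: VolumeGrid,
    kernel: SGKernel | None = None,
    weight: float = 0.1,
    mask: np.ndarray | None = None,
) -> VolumeGrid:
    """Reference-adapted weighted-mean postprocessing filter.

    Each voxel is replaced by the weight-normalised, anatomically adapted
    weighted mean of sigma over a cubic footprint (default size 10, i.e. the
    symmetric 11x11x11 neighborhood), with weights as in
    :func:`sg_fit_weights`.  This is a smoothing step, not a polynomial fit:
    the output at a voxel always lies within [min, max] of the input over its
    footprint.
    """
    if not sigma.same_geometry(reference):
        raise ValueError("sigma and reference must share geometry")
    if kernel is None:
        kernel = SGKernel("cube", 10)
    kernel = SGKernel(kernel.shape, kernel.size, kernel.degree, (reference, weight))
    if mask is None:
        mask = np.isfinite(sigma.data)
    out = np.full(sigma.shape, np.nan)
    data = np.asarray(sigma.data, dtype=float)
    for c, W, (Y,) in _iter_footprints([data], mask, kernel):
        wsum = W.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = (W * Y).sum(axis=1) / wsum
        mean[wsum <= 0] = np.nan
        out[c[:, 0], c[:, 1], c[:, 2]] = mean
    return sigma.with_data(out)


def piecewise_mean_conductivity(
    sigma: VolumeGrid, labels: TissueLabelMap
) -> tuple[VolumeGrid, pd.DataFrame]:
    """Piecewise-constant conductivity from per-tissue means.

    Every voxel of tissue t is replaced by the mean of sigma over t, the mean
    being taken over reconstructable (finite), non-negative voxels only —
    negative reconstructions are physically meaningless and would bias the
    tissue mean downward if clipped silently.  Returns the piecewise map and
    a per-tissue table (tissue, code, mean, sd, n_voxels).
    """
    if sigma.shape != labels.shape:
        raise ValueError("sigma and label map must share geometry")
    data = np.asarray(sigma.data, dtype=float)
    out = np.full(sigma.shape, np.nan)
    rows = []
    for code in labels.tissue_codes():
        sel = (labels.labels == code) & np.isfinite(data) & (data >= 0)
        n = int(sel.sum())
        if n == 0:
            name = labels.code_table.get(code, str(code))
            raise ValueError(f"tissue {name!r} (code {code}) has no reconstructable voxels")
        vals = data[sel]
        mean, sd = float(vals.mean()), float(vals.std(ddof=1)) if n > 1 else 0.0
        out[labels.labels == code] = mean
        rows.append(
            {
                "tissue": labels.code_table.get(code, str(code)),
                "code": code,
                "mean_S_per_m": mean,
                "sd_S_per_m": sd,
                "n_voxels": n,
            }
        )
    table = pd.DataFrame(rows)
    logger.info("per-tissue conductivity means:\n%s", table.to_string(index=False))
    return sigma.with_data(out), table
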