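"""E-field approximation from the complex B1+ map via Ampere's law.

The complex B1+ field is assembled from the measured magnitude and half the
transceive phase.  With the B1+-only closure (B1- = 0, Bz = 0, so Bx = B1+
and By = -i*B1+), the time-harmonic Ampere-Maxwell law
``curl(B/mu0) = (sigma + i*omega*eps) * E`` gives closed-form components

    Ex = ( i * dB1/dz) / (mu0 * tau)
    Ey = (     dB1/dz) / (mu0 * tau)
    Ez = (-i * dB1/dx - dB1/dy) / (mu0 * tau)

with ``tau = sigma + i*omega*eps`` the complex admittance per voxel.
Neglecting B1- and Bz underestimates |E| systematically; the tissue-specific
correction factors applied at the SAR stage repair this.

Derivatives use the anatomically adapted Savitzky-Golay gradient (ellipsoid
footprint) so tissue boundaries are not differentiated across.  Only |E|
reaches the SAR map, so the undetermined component signs of the closure are
unobservable downstream; |E| is also invariant to the +iwt / -iwt
time-convention choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ept import SGKernel, sg_gradient_fields
from .physics_config import ElectricalPropertiesTable, PhysicsConfig
from .volgrid import TissueLabelMap, VolumeGrid

__all__ = [
    "ComplexB1Map",
    "EFieldMap",
    "assemble_b1plus",
    "sg_gradient",
    "efield_from_b1plus",
    "expand_eps_map",
]


@dataclass
class ComplexB1Map:
    """Complex transmit field with provenance of its magnitude/phase sources."""

    b1plus: VolumeGrid  # complex
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.iscomplexobj(self.b1plus.data):
            raise ValueError("b1plus must be complex-valued")


@dataclass
class EFieldMap:
    """Three complex E-field components on a shared grid; background is 0."""

    ex: VolumeGrid
    ey: VolumeGrid
    ez: VolumeGrid

    def __post_init__(self) -> None:
        if not (self.ex.same_geometry(self.ey) and self.ex.same_geometry(self.ez)):
            raise ValueError("E-field components must share geometry")

    def magnitude_squared(self) -> np.ndarray:
        """|Ex|^2 + |Ey|^2 + |Ez|^2 (peak amplitudes)."""
        return (
            np.abs(self.ex.data) ** 2 + np.abs(self.ey.data) ** 2 + np.abs(self.ez.data) ** 2
        )

    def magnitude(self) -> VolumeGrid:
        return self.ex.with_data(np.sqrt(self.magnitude_squared()), units="V/m")


def assemble_b1plus(magnitude: VolumeGrid, transceive_phase: VolumeGrid) -> ComplexB1Map:
    """b1plus = magnitude * exp(i * phi_tr / 2).

    The transceive phase assumption: the measured phase of a low-B0-sensitivity
    sequence is twice the transmit phase, so the B1+ phase is phi_tr / 2.
    """
    if not magnitude.same_geometry(transceive_phase):
        raise ValueError("magnitude and phase must share geometry")
    mag = np.asarray(magnitude.data, dtype=float)
    if np.any(mag[np.isfinite(mag)] < 0):
        raise ValueError("B1+ magnitude must be >= 0 everywhere")
    data = mag * np.exp(0.5j * np.asarray(transceive_phase.data, dtype=float))
    b1 = VolumeGrid(data, magnitude.spacing, magnitude.origin, units=magnitude.units)
    return ComplexB1Map(
        b1, {"magnitude_units": magnitude.units, "phase_units": transceive_phase.units}
    )


def sg_gradient(
    b1field: VolumeGrid, kernel: SGKernel, mask: np.ndarray | None = None
) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid]:
    """Anatomically adapted per-axis first derivatives of a complex field, 1/m.

    Thin alias of the shared Savitzky-Golay engine; real and imaginary parts
    are fit with shared weights.
    """
    return sg_gradient_fields(b1field, kernel, mask=mask)


def expand_eps_map(
    eps_table: ElectricalPropertiesTable, labels: TissueLabelMap
) -> VolumeGrid:
    """Piecewise-constant relative permittivity over the label map (background 0)."""
    codes = labels.tissue_codes()
    eps_table.validate_covers(codes)
    out = np.zeros(labels.shape)
    for code in codes:
        out[labels.labels == code] = eps_table.eps_r[code]
    return VolumeGrid(out, labels.spacing, labels.origin, units="1")


def efield_from_b1plus(
    b1: ComplexB1Map,
    sigma: VolumeGrid,
    eps_table: ElectricalPropertiesTable,
    labels: TissueLabelMap,
    cfg: PhysicsConfig,
    kernel: SGKernel | None = None,
) -> EFieldMap:
    """Closed-form E-field components from B1+ derivatives and tissue properties.

    ``sigma`` is the piecewise-mean conductivity map; permittivity is the
    literature table expanded over the labels.  Derivatives are evaluated
    with the given kernel (default: ellipsoid of size 4 adapted on the label
    map).  Background voxels are zero; voxels where the derivative fit failed
    are NaN in all three components.
    """
    grid = b1.b1plus
    if not (grid.same_geometry(sigma) and grid.same_geometry(labels.as_grid())):
        raise ValueError("B1+, sigma, and labels must share geometry")
    fg = labels.foreground()
    if kernel is None:
        kernel = SGKernel("ellipsoid", 4, adaptation=(labels.as_grid(), 0.05))

    # Under the -iwt convention the phasor, the closure (By = +i B1+), and
    # the admittance all conjugate, so the whole chain is the conjugate of
    # the +iwt result; |E| and SAR are identical by construction.
    conjugate = cfg.time_convention == "-iwt"
    dx, dy, dz = sg_gradient(grid, kernel, mask=fg)

    eps_map = expand_eps_map(eps_table, labels)
    eps0 = 8.8541878128e-12
    tau = np.asarray(sigma.data, dtype=complex) + 1j * cfg.omega * eps0 * eps_map.data
    bad = fg & (tau == 0)
    if np.any(bad):
        raise ValueError(f"zero complex admittance at {int(bad.sum())} foreground voxels")

    denom = cfg.mu0 * tau
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = (1j * dz.data) / denom
        ey = dz.data / denom
        ez = (-1j * dx.data - dy.data) / denom
    if conjugate:
        ex, ey, ez = np.conj(ex), np.conj(ey), np.conj(ez)
    for comp in (ex, ey, ez):
        comp[~fg] = 0.0
    units = "V/m" if grid.units in ("T", "tesla") else "a.u."
    return EFieldMap(
        grid.with_data(ex, units=units),
        grid.with_data(ey, units=units),
        grid.with_data(ez, units=units),
    )
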