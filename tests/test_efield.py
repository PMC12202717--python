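import numpy as np
import pytest
from hypothesis import given, strategies as st

from imsar import (
    ElectricalPropertiesTable,
    PhysicsConfig,
    SGKernel,
    VolumeGrid,
    assemble_b1plus,
    efield_from_b1plus,
    sg_gradient,
)
from imsar.physics_config import MU0
from imsar.volgrid import TissueLabelMap


def grid_meters(shape, spacing):
    axes = [np.arange(n) * s * 1e-3 for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def one_tissue(shape, spacing, sigma=1.0, eps_r=1.0):
    labels = TissueLabelMap(np.ones(shape, np.int32), spacing)
    sig = VolumeGrid(np.full(shape, sigma), spacing, units="S/m")
    table = ElectricalPropertiesTable({1: sigma}, {1: eps_r})
    return labels, sig, table


def test_assemble_closed_forms():
    mag = VolumeGrid(np.full((4, 4, 4), 1.0), (2, 2, 2))
    pha = VolumeGrid(np.zeros((4, 4, 4)), (2, 2, 2), units="rad")
    b1 = assemble_b1plus(mag, pha)
    assert np.allclose(b1.b1plus.data, 1.0 + 0j)
    b1b = assemble_b1plus(mag.with_data(np.full((4, 4, 4), 2.0)),
                          pha.with_data(np.full((4, 4, 4), np.pi)))
    assert np.allclose(b1b.b1plus.data, 2j)


def test_assemble_rejects_negative_magnitude():
    mag = VolumeGrid(np.full((3, 3, 3), -1.0), (1, 1, 1))
    pha = VolumeGrid(np.zeros((3, 3, 3)), (1, 1, 1), units="rad")
    with pytest.raises(ValueError):
        assemble_b1plus(mag, pha)


@given(scale=st.floats(0.1, 10.0), phase=st.floats(-3.0, 3.0))
def test_assemble_magnitude_preserved(scale, phase):
    mag = VolumeGrid(np.full((3, 3, 3), scale), (1, 1, 1))
    pha = VolumeGrid(np.full((3, 3, 3), phase), (1, 1, 1), units="rad")
    b1 = assemble_b1plus(mag, pha)
    assert np.allclose(np.abs(b1.b1plus.data), scale)
    assert np.allclose(np.angle(b1.b1plus.data), phase / 2)


def test_gradient_of_linear_and_quadratic_fields():
    shape, spacing = (12, 12, 12), (2.0, 2.0, 2.5)
    xx, yy, zz = grid_meters(shape, spacing)
    a = 3.0
    lin = VolumeGrid(a * xx, spacing)
    gx, gy, gz = sg_gradient(lin, SGKernel("ellipsoid", 4))
    interior = np.s_[4:-4, 4:-4, 4:-4]
    assert np.allclose(gx.data[interior], a, rtol=1e-9)
    assert np.nanmax(np.abs(gy.data[interior])) < 1e-9
    assert np.nanmax(np.abs(gz.data[interior])) < 1e-9
    quad = VolumeGrid(xx**2 + 2 * yy * zz, spacing)
    qx, qy, qz = sg_gradient(quad, SGKernel("ellipsoid", 4))
    assert np.allclose(qx.data[interior], 2 * xx[interior], rtol=1e-8, atol=1e-12)
    assert np.allclose(qy.data[interior], 2 * zz[interior], rtol=1e-8, atol=1e-12)
    assert np.allclose(qz.data[interior], 2 * yy[interior], rtol=1e-8, atol=1e-12)


def test_gradient_of_constant_complex_field():
    v = VolumeGrid(np.full((10, 10, 10), 1 + 2j), (2, 2, 2))
    gx, gy, gz = sg_gradient(v, SGKernel("ellipsoid", 4))
    interior = np.s_[4:-4, 4:-4, 4:-4]
    for g in (gx, gy, gz):
        assert np.nanmax(np.abs(g.data[interior])) < 1e-9


def test_constant_b1_gives_zero_efield(phys):
    shape, spacing = (12, 12, 12), (2, 2, 2)
    labels, sig, table = one_tissue(shape, spacing)
    mag = VolumeGrid(np.ones(shape), spacing)
    pha = VolumeGrid(np.zeros(shape), spacing, units="rad")
    E = efield_from_b1plus(assemble_b1plus(mag, pha), sig, table, labels, phys)
    interior = np.s_[4:-4, 4:-4, 4:-4]
    assert np.nanmax(E.magnitude().data[interior]) < 1e-9


def test_linear_b1_matches_closed_form():
    """B1+ = z with sigma = 1 S/m: |Ex| = |Ey| = 1/(mu0 |tau|), Ez = 0."""
    shape, spacing = (12, 12, 16), (2.0, 2.0, 2.0)
    _, _, zz = grid_meters(shape, spacing)
    labels, sig, table = one_tissue(shape, spacing, sigma=1.0, eps_r=1.0)
    cfg = PhysicsConfig()
    b1 = assemble_b1plus(VolumeGrid(zz + 1.0, spacing), VolumeGrid(np.zeros(shape), spacing, units="rad"))
    E = efield_from_b1plus(b1, sig, table, labels, cfg)
    tau = 1.0 + 1j * cfg.omega * 8.8541878128e-12 * 1.0
    expected = 1.0 / (MU0 * abs(tau))
    interior = np.s_[4:-4, 4:-4, 4:-4]
    assert np.allclose(np.abs(E.ex.data[interior]), expected, rtol=1e-8)
    assert np.allclose(np.abs(E.ey.data[interior]), expected, rtol=1e-8)
    assert np.nanmax(np.abs(E.ez.data[interior])) < expected * 1e-8


def test_admittance_scaling_halves_e(phys):
    """Doubling sigma (eps contribution negligible) halves |E| voxelwise."""
    shape, spacing = (10, 10, 14), (2.3, 2.3, 2.5)
    _, _, zz = grid_meters(shape, spacing)
    b1 = assemble_b1plus(VolumeGrid(zz + 1.0, spacing), VolumeGrid(np.zeros(shape), spacing, units="rad"))
    interior = np.s_[4:-4, 4:-4, 4:-4]
    mags = []
    for s in (1.0, 2.0):
        labels, sig, table = one_tissue(shape, spacing, sigma=s)
        E = efield_from_b1plus(b1, sig, table, labels, phys)
        mags.append(E.magnitude().data[interior])
    tau1 = abs(1.0 + 1j * phys.omega * 8.8541878128e-12)
    tau2 = abs(2.0 + 1j * phys.omega * 8.8541878128e-12)
    assert np.allclose(mags[0] / mags[1], tau2 / tau1, rtol=1e-9)


def test_linearity_in_b1(phys, rng):
    shape, spacing = (10, 10, 10), (2, 2, 2)
    labels, sig, table = one_tissue(shape, spacing, sigma=0.5, eps_r=50.0)
    mag = VolumeGrid(1.0 + 0.1 * rng.random(shape), spacing)
    pha = VolumeGrid(0.2 * rng.random(shape), spacing, units="rad")
    E1 = efield_from_b1plus(assemble_b1plus(mag, pha), sig, table, labels, phys)
    E2 = efield_from_b1plus(assemble_b1plus(mag.with_data(3.0 * mag.data), pha), sig, table, labels, phys)
    interior = np.s_[4:-4, 4:-4, 4:-4]
    assert np.allclose(E2.ex.data[interior], 3.0 * E1.ex.data[interior], rtol=1e-9)
    assert np.allclose(E2.ez.data[interior], 3.0 * E1.ez.data[interior], rtol=1e-9)


def test_time_convention_invariance_of_magnitude(rng):
    shape, spacing = (10, 10, 10), (2, 2, 2)
    labels, sig, table = one_tissue(shape, spacing, sigma=0.6, eps_r=60.0)
    mag = VolumeGrid(1.0 + 0.05 * rng.random(shape), spacing)
    pha = VolumeGrid(0.3 * rng.random(shape), spacing, units="rad")
    b1 = assemble_b1plus(mag, pha)
    Ep = efield_from_b1plus(b1, sig, table, labels, PhysicsConfig(time_convention="+iwt"))
    Em = efield_from_b1plus(b1, sig, table, labels, PhysicsConfig(time_convention="-iwt"))
    interior = np.s_[4:-4, 4:-4, 4:-4]
    assert np.allclose(Ep.magnitude().data[interior], Em.magnitude().data[interior], rtol=1e-12)


def test_components_match_finite_difference_curl(phys):
    """Independent oracle: FD curl of (B1, -iB1, 0) / (mu0 tau) on a quadratic B1."""
    shape, spacing = (14, 14, 14), (2.0, 2.0, 2.0)
    xx, yy, zz = grid_meters(shape, spacing)
    b1_data = (1.0 + 5.0 * xx + 3.0 * yy**2 + 2.0 * zz + 4.0 * xx * zz).astype(complex)
    labels, sig, table = one_tissue(shape, spacing, sigma=0.8, eps_r=40.0)
    b1 = assemble_b1plus(VolumeGrid(np.abs(b1_data), spacing),
                         VolumeGrid(2 * np.angle(b1_data), spacing, units="rad"))
    E = efield_from_b1plus(b1, sig, table, labels, phys)

    h = np.asarray(spacing) * 1e-3
    dBdx, dBdy, dBdz = np.gradient(b1_data, h[0], h[1], h[2])
    tau = 0.8 + 1j * phys.omega * 8.8541878128e-12 * 40.0
    ex = 1j * dBdz / (MU0 * tau)
    ey = dBdz / (MU0 * tau)
    ez = (-1j * dBdx - dBdy) / (MU0 * tau)
    interior = np.s_[4:-4, 4:-4, 4:-4]
    assert np.allclose(E.ex.data[interior], ex[interior], rtol=1e-6, atol=1e-9)
    assert np.allclose(E.ey.data[interior], ey[interior], rtol=1e-6, atol=1e-9)
    assert np.allclose(E.ez.data[interior], ez[interior], rtol=1e-6, atol=1e-9)
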