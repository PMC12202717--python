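import numpy as np
import pytest

from imsar import (
    PhantomSpec,
    SGKernel,
    VolumeGrid,
    add_noise,
    conductivity_from_phase,
    ept_postprocess,
    forward_transceive_phase,
    make_phantom,
    piecewise_mean_conductivity,
    sg_fit_weights,
    sg_laplacian,
)
from imsar.ept import _design_matrix
from imsar.synthetic_phantom import interior_mask
from imsar.volgrid import TissueLabelMap


def quadratic_phase(shape, spacing_mm, a):
    """phi = a * |r|^2 with r in meters from the volume centre; Laplacian 6a."""
    axes = [((np.arange(n) - n / 2) * s * 1e-3) for n, s in zip(shape, spacing_mm)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return VolumeGrid(a * (xx**2 + yy**2 + zz**2), spacing_mm, units="rad")


# ---------------------------------------------------------------------------
# adaptation weights
# ---------------------------------------------------------------------------

def test_uniform_reference_gives_unit_weights():
    ref = np.full(27, 5.0)
    w = sg_fit_weights(np.array(5.0), ref, np.ones(27, bool), 0.05, ref_range=0.0)
    assert np.allclose(w, 1.0)


def test_infinite_weight_parameter_limit():
    ref = np.linspace(0, 1, 27)
    w = sg_fit_weights(np.array(0.0), ref, np.ones(27, bool), np.inf, ref_range=1.0)
    assert np.allclose(w, 1.0)


def test_step_reference_blocks_cross_boundary():
    """With w = 0.05 a two-intensity step suppresses cross-side weights by >10^3."""
    ref = np.array([0.0] * 13 + [1.0] * 14)
    w = sg_fit_weights(np.array(0.0), ref, np.ones(27, bool), 0.05, ref_range=1.0)
    same, cross = w[:13], w[13:]
    assert np.allclose(same, 1.0)
    assert cross.max() < 1e-3 * same.min()
    assert ((w >= 0) & (w <= 1)).all()


def test_background_voxels_weigh_zero():
    fg = np.array([True] * 10 + [False] * 17)
    w = sg_fit_weights(np.array(0.0), np.zeros(27), fg, 0.05, ref_range=1.0)
    assert np.allclose(w[10:], 0.0) and np.allclose(w[:10], 1.0)


# ---------------------------------------------------------------------------
# SG Laplacian
# ---------------------------------------------------------------------------

def test_kernel_conventions():
    assert SGKernel("cuboid", 5).offsets().shape[0] == 125
    assert SGKernel("cube", 10).offsets().shape[0] == 11**3
    n_ell = SGKernel("ellipsoid", 4).offsets().shape[0]
    assert 11 < n_ell < 9**3  # masked to the ellipsoid
    with pytest.raises(ValueError):
        SGKernel("cuboid", 5, degree=3)
    with pytest.raises(ValueError):
        SGKernel("cuboid", 1)  # too few voxels for 10 coefficients


def test_constant_phase_has_zero_laplacian():
    v = VolumeGrid(np.full((12, 12, 12), 2.2), (2, 2, 2), units="rad")
    lap = sg_laplacian(v, SGKernel("cuboid", 5))
    interior = np.zeros(v.shape, bool)
    interior[2:-2, 2:-2, 2:-2] = True
    # roundoff of the fit coefficients is amplified by 1/h^2; anything below
    # 1e-7 rad/m^2 corresponds to < 1e-10 S/m
    assert np.nanmax(np.abs(lap.data[interior])) < 1e-7


def test_quadratic_phase_reproduced_exactly():
    """Degree-2 fits reproduce quadratics: Laplacian of a|r|^2 is 6a to precision."""
    a = 100.0  # rad/m^2
    v = quadratic_phase((16, 16, 16), (2.3, 2.3, 2.5), a)
    lap = sg_laplacian(v, SGKernel("cuboid", 5))
    interior = np.zeros(v.shape, bool)
    interior[2:-2, 2:-2, 2:-2] = True
    assert np.allclose(lap.data[interior], 6 * a, rtol=1e-9)


def test_sinusoid_laplacian_small_k():
    spacing = (1.0, 1.0, 1.0)
    n = 24
    k = 0.15 / 1e-3  # k*spacing = 0.15 < 0.2
    x = np.arange(n) * 1e-3
    data = np.sin(k * x)[:, None, None] * np.ones((1, n, n))
    v = VolumeGrid(data, spacing, units="rad")
    lap = sg_laplacian(v, SGKernel("cuboid", 5))
    interior = np.s_[4:-4, 4:-4, 4:-4]
    expected = -(k**2) * data[interior]
    assert np.allclose(lap.data[interior], expected, rtol=0.01)


def test_laplacian_equals_dense_wls_oracle(rng):
    """Batched engine vs an independent per-voxel weighted lstsq on 9^3."""
    shape = (9, 9, 9)
    spacing = (2.0, 2.0, 2.5)
    data = rng.normal(size=shape)
    ref = VolumeGrid(rng.random(shape), spacing)
    mask = rng.random(shape) > 0.15
    kernel = SGKernel("cuboid", 5, adaptation=(ref, 0.3))
    lap = sg_laplacian(VolumeGrid(data, spacing, units="rad"), kernel, mask=mask)

    offs = kernel.offsets()
    Phi = _design_matrix(offs)
    h = np.asarray(spacing) * 1e-3
    rng_ref = ref.data[mask]
    ref_range = rng_ref.max() - rng_ref.min()
    for c in [(4, 4, 4), (2, 6, 3), (1, 1, 7)]:
        if not mask[c]:
            continue
        rows, w, y = [], [], []
        for p, off in enumerate(offs):
            q = tuple(np.add(c, off))
            if any(i < 0 or i >= s for i, s in zip(q, shape)) or not mask[q]:
                continue
            wj = np.exp(
                -((ref.data[q] - ref.data[c]) ** 2) / (2 * (0.3 * ref_range) ** 2)
            )
            rows.append(Phi[p])
            w.append(wj)
            y.append(data[q])
        rows, w, y = np.array(rows), np.array(w), np.array(y)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(rows * sw[:, None], y * sw, rcond=None)
        expected = 2 * (coef[4] / h[0] ** 2 + coef[5] / h[1] ** 2 + coef[6] / h[2] ** 2)
        assert lap.data[c] == pytest.approx(expected, rel=1e-10)


def test_isolated_voxel_is_unreconstructable():
    mask = np.zeros((9, 9, 9), bool)
    mask[4, 4, 4] = True
    v = VolumeGrid(np.ones((9, 9, 9)), (2, 2, 2), units="rad")
    lap = sg_laplacian(v, SGKernel("cuboid", 5), mask=mask)
    assert np.isnan(lap.data[4, 4, 4])


# ---------------------------------------------------------------------------
# conductivity
# ---------------------------------------------------------------------------

def test_constant_phase_gives_zero_sigma(phys):
    v = VolumeGrid(np.full((10, 10, 10), 1.0), (2, 2, 2), units="rad")
    sig = conductivity_from_phase(v, SGKernel("cuboid", 5), phys)
    assert np.nanmax(np.abs(sig.data[2:-2, 2:-2, 2:-2])) < 1e-12


def test_uniform_sigma_recovery(phys, small_sphere):
    spec, labels, sigma, _ = small_sphere
    phase = forward_transceive_phase(sigma, labels, phys)
    rec = conductivity_from_phase(phase, SGKernel("cuboid", 5), phys, mask=labels.foreground())
    interior = interior_mask(labels, 1, 4)
    assert np.allclose(rec.data[interior], 0.5, rtol=0.01)


def test_noise_response_is_monotone(phys):
    """Reconstruction SD in a uniform region grows with phase-noise SD."""
    labels, sigma, _ = make_phantom(
        PhantomSpec(kind="sphere", shape=(28, 28, 28), spacing=(2.3, 2.3, 2.5),
                    region_sigma={1: 0.5}, noise_sd_phase=0.0)
    )
    phase = forward_transceive_phase(sigma, labels, phys)
    interior = interior_mask(labels, 1, 4)
    sds = []
    for sd in (0.002, 0.01, 0.05):
        noisy = add_noise(phase, sd, 11)
        rec = conductivity_from_phase(noisy, SGKernel("cuboid", 5), phys,
                                      mask=labels.foreground())
        sds.append(np.nanstd(rec.data[interior]))
    assert sds[0] < sds[1] < sds[2]


# ---------------------------------------------------------------------------
# postprocessing + piecewise means
# ---------------------------------------------------------------------------

def test_postprocess_uniform_unchanged():
    v = VolumeGrid(np.full((14, 14, 14), 0.7), (2, 2, 2), units="S/m")
    ref = VolumeGrid(np.ones((14, 14, 14)), (2, 2, 2))
    out = ept_postprocess(v, ref, SGKernel("cube", 6), 0.1)
    assert np.allclose(out.data, 0.7)


def test_postprocess_contracts_variance(rng):
    base = np.full((16, 16, 16), 1.0)
    noisy = base + (rng.random(base.shape) < 0.1) * rng.choice([-0.5, 0.5], base.shape)
    v = VolumeGrid(noisy, (2, 2, 2), units="S/m")
    ref = VolumeGrid(np.ones_like(base), (2, 2, 2))
    out = ept_postprocess(v, ref, SGKernel("cube", 6), 0.1)
    assert np.nanstd(out.data) < np.std(noisy)
    assert np.nanmin(out.data) >= noisy.min() - 1e-12
    assert np.nanmax(out.data) <= noisy.max() + 1e-12


def test_postprocess_adaptation_blocks_cross_region_mixing():
    shape = (20, 12, 12)
    sigma = np.where(np.arange(shape[0])[:, None, None] < 10, 0.3, 1.5) * np.ones(shape)
    ref = np.where(np.arange(shape[0])[:, None, None] < 10, 0.0, 1.0) * np.ones(shape)
    v = VolumeGrid(sigma, (2, 2, 2), units="S/m")
    out = ept_postprocess(v, VolumeGrid(ref, (2, 2, 2)), SGKernel("cube", 6), 0.1)
    left = out.data[:10].mean()
    right = out.data[10:].mean()
    assert left == pytest.approx(0.3, rel=0.02)
    assert right == pytest.approx(1.5, rel=0.02)


def test_piecewise_mean_is_identity_on_piecewise_input():
    labels = TissueLabelMap(
        np.concatenate([np.ones((4, 4, 4)), 2 * np.ones((4, 4, 4))]).astype(np.int32),
        (2, 2, 2),
    )
    sigma = VolumeGrid(np.where(labels.labels == 1, 0.5, 0.9), (2, 2, 2), units="S/m")
    out, table = piecewise_mean_conductivity(sigma, labels)
    assert np.allclose(out.data, sigma.data)
    assert set(table["code"]) == {1, 2}


def test_piecewise_mean_arithmetic_and_negative_exclusion():
    labels = TissueLabelMap(np.ones((3, 1, 1), np.int32), (1, 1, 1))
    sigma = VolumeGrid(np.array([0.5, 0.6, 0.7]).reshape(3, 1, 1), (1, 1, 1), units="S/m")
    out, table = piecewise_mean_conductivity(sigma, labels)
    assert np.allclose(out.data, 0.6)
    # a negative voxel is excluded from the mean but still assigned the mean
    sigma2 = VolumeGrid(np.array([0.5, -0.1, 0.7]).reshape(3, 1, 1), (1, 1, 1), units="S/m")
    out2, t2 = piecewise_mean_conductivity(sigma2, labels)
    assert np.allclose(out2.data, 0.6)
    assert t2.loc[0, "n_voxels"] == 2


def test_piecewise_mean_errors_on_unreconstructable_tissue():
    labels = TissueLabelMap(np.ones((2, 2, 2), np.int32), (1, 1, 1))
    sigma = VolumeGrid(np.full((2, 2, 2), np.nan), (1, 1, 1), units="S/m")
    with pytest.raises(ValueError, match="gray_matter"):
        piecewise_mean_conductivity(sigma, labels)
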