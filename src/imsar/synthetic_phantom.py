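"""Forward-consistent digital phantoms for the SAR mapping pipeline.

Three phantom families are emulated:

* ``sphere`` — a homogeneous sphere mimicking a distilled-water QA phantom
  (conductivity 0.01 S/m, relative permittivity 80);
* ``vials6`` — six saline compartments (cylindrical vials) in a water-filled
  cylindrical container, spanning roughly 0.1-0.75 S/m;
* ``brainlike`` — concentric GM/WM shells with CSF ventricles and a thin CSF
  rim, using the literature brain tissue properties.

The forward transceive phase is built from the inverse model's own identity:
within each homogeneous region

    phi_tr(r) = (mu0 * omega * sigma_region / 3) * |r - c_region|^2 + offset

whose analytic Laplacian is exactly ``2 * mu0 * omega * sigma`` — so a
noiseless phantom is recovered exactly by the Helmholtz-EPT inverse at region
interiors.  Phase continuity across region boundaries is deliberately NOT
enforced; boundary voxels are excluded from recovery statements, mirroring
the boundary-error behaviour of real reconstructions.

Everything is a pure function of the :class:`PhantomSpec` (noise included),
so fixtures are reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy import ndimage

from .physics_config import PhysicsConfig, DEFAULT_SIGMA, DEFAULT_EPSR
from .volgrid import TissueLabelMap, VolumeGrid, DEFAULT_CODE_TABLE

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "forward_transceive_phase",
    "forward_b1_magnitude",
    "add_noise",
    "interior_mask",
    "VIALS6_SIGMA",
]

#: Probe-measured saline conductivities of the six vials, S/m.
VIALS6_SIGMA = (0.16, 0.32, 0.39, 0.46, 0.56, 0.75)

#: Distilled water at room temperature and 128 MHz.
WATER_SIGMA, WATER_EPSR = 0.01, 80.0


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom.

    Default noise levels: phase SD 0.01 rad, 1% relative magnitude noise,
    seed 1234.
    """

    kind: str = "vials6"  # sphere | vials6 | brainlike
    shape: tuple[int, int, int] = (128, 128, 35)
    spacing: tuple[float, float, float] = (2.3, 2.3, 2.5)  # mm
    region_sigma: Mapping[int, float] | None = None  # S/m, keyed by label
    region_epsr: Mapping[int, float] | None = None
    geometry: Mapping[str, float] = field(default_factory=dict)
    noise_sd_phase: float = 0.01  # rad
    noise_sd_magnitude: float = 0.01  # relative
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "vials6", "brainlike"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.noise_sd_phase < 0 or self.noise_sd_magnitude < 0:
            raise ValueError("noise SDs must be >= 0")
        if any(s < 1 for s in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("invalid grid geometry")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_sigma"] = None if self.region_sigma is None else dict(self.region_sigma)
        d["region_epsr"] = None if self.region_epsr is None else dict(self.region_epsr)
        return d


def _grid_mm(shape, spacing):
    axes = [np.arange(n, dtype=float) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _cylinder(xx, yy, zz, cx, cy, radius, z0, z1):
    return ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2) & (zz >= z0) & (zz <= z1)


def make_phantom(spec: PhantomSpec) -> tuple[TissueLabelMap, VolumeGrid, VolumeGrid]:
    """Build the label map and true sigma / eps_r maps for a phantom spec.

    Regions are disjoint by construction (later regions overwrite earlier
    ones would be an error; geometry is designed non-overlapping and this is
    asserted).  Returns ``(labels, sigma_true, epsr_true)`` with sigma
    piecewise constant at the region values.
    """
    shape, spacing = tuple(spec.shape), tuple(spec.spacing)
    xx, yy, zz = _grid_mm(shape, spacing)
    fov = [(n - 1) * s for n, s in zip(shape, spacing)]
    cx, cy, cz = (f / 2.0 for f in fov)

    labels = np.zeros(shape, dtype=np.int32)
    code_table = {0: "background"}

    if spec.kind == "sphere":
        radius = float(spec.geometry.get("radius_mm", 0.4 * min(fov)))
        sph = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= radius**2
        labels[sph] = 1
        code_table[1] = "water"
        sigma_by_label = {1: WATER_SIGMA}
        epsr_by_label = {1: WATER_EPSR}

    elif spec.kind == "vials6":
        container_r = float(spec.geometry.get("container_radius_mm", 60.0))
        vial_r = float(spec.geometry.get("vial_radius_mm", 16.0))
        ring_r = float(spec.geometry.get("ring_radius_mm", 38.0))
        z0 = float(spec.geometry.get("z0_mm", 0.05 * fov[2]))
        z1 = float(spec.geometry.get("z1_mm", 0.95 * fov[2]))
        # container of distilled water, label 7
        cont = _cylinder(xx, yy, zz, cx, cy, container_r, z0, z1)
        labels[cont] = 7
        code_table[7] = "water"
        vial_sigma = VIALS6_SIGMA
        sigma_by_label = {7: WATER_SIGMA}
        epsr_by_label = {7: WATER_EPSR}
        for k in range(6):
            ang = 2.0 * np.pi * k / 6.0
            vx, vy = cx + ring_r * np.cos(ang), cy + ring_r * np.sin(ang)
            vial = _cylinder(xx, yy, zz, vx, vy, vial_r, z0, z1)
            overlap = vial & ~np.isin(labels, (0, 7))
            if overlap.any():
                raise ValueError(f"vial {k + 1} overlaps a previous region")
            labels[vial] = k + 1
            code_table[k + 1] = f"vial_{k + 1}"
            sigma_by_label[k + 1] = vial_sigma[k]
            epsr_by_label[k + 1] = WATER_EPSR
    else:  # brainlike
        # concentric ellipsoids: thin CSF rim, GM shell, WM core, plus two
        # CSF "ventricles" inside the WM
        a = np.asarray([0.44 * f for f in fov])  # outer semi-axes, mm
        r = np.sqrt(
            ((xx - cx) / a[0]) ** 2 + ((yy - cy) / a[1]) ** 2 + ((zz - cz) / a[2]) ** 2
        )
        labels[r <= 1.0] = 3  # CSF rim
        labels[r <= 0.92] = 1  # GM shell
        labels[r <= 0.70] = 2  # WM core
        for sx in (-1.0, 1.0):
            vent = (
                ((xx - (cx + sx * 0.12 * fov[0])) / (0.10 * fov[0])) ** 2
                + ((yy - cy) / (0.16 * fov[1])) ** 2
                + ((zz - cz) / (0.16 * fov[2])) ** 2
            ) <= 1.0
            labels[vent] = 3
        code_table.update({1: "gray_matter", 2: "white_matter", 3: "csf"})
        sigma_by_label = dict(DEFAULT_SIGMA)
        epsr_by_label = dict(DEFAULT_EPSR)

    if spec.region_sigma is not None:
        sigma_by_label.update({int(k): float(v) for k, v in spec.region_sigma.items()})
    if spec.region_epsr is not None:
        epsr_by_label.update({int(k): float(v) for k, v in spec.region_epsr.items()})
    if any(v < 0 for v in sigma_by_label.values()):
        raise ValueError("region conductivities must be >= 0")

    sigma = np.zeros(shape)
    epsr = np.zeros(shape)
    for code in np.unique(labels):
        if code == 0:
            continue
        sigma[labels == code] = sigma_by_label[int(code)]
        epsr[labels == code] = epsr_by_label[int(code)]

    lab = TissueLabelMap(labels, spacing, code_table=code_table)
    return (
        lab,
        VolumeGrid(sigma, spacing, units="S/m"),
        VolumeGrid(epsr, spacing, units="1"),
    )


def forward_transceive_phase(
    sigma_map: VolumeGrid, labels: TissueLabelMap, cfg: PhysicsConfig
) -> VolumeGrid:
    """Piecewise-quadratic transceive phase consistent with the Helmholtz inverse.

    Inside each labelled region with conductivity sigma the phase is
    ``(mu0*omega*sigma/3) * |r - c|^2 + offset`` (r in meters, c the region
    centroid), whose Laplacian is exactly ``2*mu0*omega*sigma``.  The
    per-region offset (0.1 rad * label code) makes boundary discontinuities
    explicit.  Background phase is 0.
    """
    if np.any(sigma_map.data < 0):
        raise ValueError("conductivity must be >= 0 everywhere")
    shape, spacing = sigma_map.shape, sigma_map.spacing
    xx, yy, zz = _grid_mm(shape, spacing)
    phase = np.zeros(shape)
    k = cfg.mu0 * cfg.omega / 3.0
    for code in labels.tissue_codes():
        sel = labels.labels == code
        cx, cy, cz = (float(g[sel].mean()) for g in (xx, yy, zz))
        r2_m = ((xx[sel] - cx) ** 2 + (yy[sel] - cy) ** 2 + (zz[sel] - cz) ** 2) * 1e-6
        sig = float(np.mean(sigma_map.data[sel]))
        phase[sel] = k * sig * r2_m + 0.1 * code
    return VolumeGrid(phase, spacing, sigma_map.origin, units="rad")


def forward_b1_magnitude(
    labels: TissueLabelMap,
    model: str = "radial-smooth",
    amplitude: float = 1.0,
    units: str = "a.u.",
) -> VolumeGrid:
    """Smooth birdcage-like B1+ magnitude over the phantom.

    ``uniform`` gives a flat foreground at ``amplitude``; ``radial-smooth``
    is a centre-bright Gaussian profile (maximum at the object centroid,
    monotone non-increasing along rays, C-infinity) emulating the centre
    brightening of a quadrature birdcage at 3 T.  An all-zero map (amplitude
    0) is rejected because it cannot seed the E-field stage.
    """
    if model not in ("uniform", "radial-smooth"):
        raise ValueError(f"unknown B1 model {model!r}")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0 for downstream E-field use")
    shape, spacing = labels.shape, labels.spacing
    fg = labels.foreground()
    if model == "uniform":
        mag = np.where(fg, amplitude, 0.0)
    else:
        xx, yy, zz = _grid_mm(shape, spacing)
        cx, cy, cz = (float(g[fg].mean()) for g in (xx, yy, zz)) if fg.any() else (0, 0, 0)
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        extent = max(float(np.sqrt(r2[fg].max())), 1.0) if fg.any() else 1.0
        s = 0.75 * extent
        mag = amplitude * np.exp(-r2 / (2.0 * s**2))
        mag[~fg] = 0.0
    return VolumeGrid(mag, spacing, labels.origin, units=units)


#: T1-like reference intensities per region name.  Spatially adjacent
#: compartments get well-separated levels (vials alternate between two
#: levels around the ring) so the anatomical adaptation weights can
#: distinguish every boundary, which is what the real anatomical reference
#: image provides.
T1_LEVELS = {
    "background": 0.0,
    "gray_matter": 0.6,
    "white_matter": 1.0,
    "csf": 0.1,
    "water": 0.15,
    "vial_1": 0.55,
    "vial_2": 1.0,
    "vial_3": 0.55,
    "vial_4": 1.0,
    "vial_5": 0.55,
    "vial_6": 1.0,
}


def t1_like_reference(
    labels: TissueLabelMap, levels: Mapping[int, float] | None = None
) -> VolumeGrid:
    """Piecewise-constant T1-weighted-like anatomical reference image.

    Emulates the role of the anatomical (MPRAGE) reference in filter
    adaptation: a distinct intensity per compartment, well separated across
    every spatially adjacent pair.  ``levels`` overrides intensities by
    label code; defaults come from the region names in the code table.
    """
    out = np.zeros(labels.shape)
    for code in labels.tissue_codes():
        if levels is not None and code in levels:
            val = float(levels[code])
        else:
            name = labels.code_table.get(code, "")
            val = T1_LEVELS.get(name, 0.5 + 0.5 * (code % 2))
        out[labels.labels == code] = val
    return VolumeGrid(out, labels.spacing, labels.origin, units="a.u.")


def add_noise(v: VolumeGrid, sd: float, seed: int) -> VolumeGrid:
    """Additive zero-mean Gaussian noise in the units of ``v``; seeded."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return v.with_data(v.data.copy())
    rng = np.random.default_rng(seed)
    return v.with_data(v.data + rng.normal(0.0, sd, size=v.shape))


def interior_mask(labels: TissueLabelMap, code: int, margin_voxels: int) -> np.ndarray:
    """Region voxels at Chebyshev distance >= margin from any boundary.

    Used to exclude the boundary layer (where the piecewise forward phase is
    discontinuous and the SG footprint mixes regions) from recovery
    statistics.
    """
    sel = labels.labels == code
    if margin_voxels <= 0:
        return sel
    struct = np.ones((3, 3, 3), dtype=bool)
    return ndimage.binary_erosion(sel, structure=struct, iterations=margin_voxels)
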