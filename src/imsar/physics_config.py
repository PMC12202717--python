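"""Physical constants, tissue property tables, and pipeline configuration.

Every physical symbol used by the pipeline lives here: the Larmor angular
frequency omega = 2*pi*f0, the vacuum permeability mu0, the tissue mass
density rho, literature electrical properties per tissue, and the
tissue-specific multiplicative correction factors that repair the systematic
SAR underestimation of the B1+-only field closure.

Configuration is one human-editable YAML file with sections ``physics``,
``tissues``, ``correction``, ``filters``, ``pipeline``; absent keys fall back
to the defaults below.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

logger = logging.getLogger("imsar")

__all__ = [
    "PhysicsConfig",
    "ElectricalPropertiesTable",
    "CorrectionFactorTable",
    "FilterParams",
    "EffectiveConfig",
    "ConfigError",
    "load_config",
    "default_config",
    "dump_config",
    "MU0",
]

#: Vacuum permeability, H/m.
MU0 = 4.0e-7 * math.pi

#: Literature electrical conductivity (S/m) at 128 MHz per tissue code.
DEFAULT_SIGMA = {1: 0.59, 2: 0.34, 3: 2.14}  # GM, WM, CSF

# Relative permittivity at 128 MHz from the standard tissue-property
# parametrisation of the dielectric literature database (same source as the
# conductivities above): GM 73.5, WM 52.5, CSF 84.0.
DEFAULT_EPSR = {1: 73.5, 2: 52.5, 3: 84.0}

#: Tissue-specific SAR correction factors (voxelwise map).
DEFAULT_SAR_FACTORS = {1: 3.08, 2: 1.79, 3: 2.59}
#: Tissue-specific 10-g SAR correction factors.
DEFAULT_SAR10G_FACTORS = {1: 2.11, 2: 2.06, 3: 1.95}

TISSUE_NAMES = {1: "gray_matter", 2: "white_matter", 3: "csf"}


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration input."""


@dataclass(frozen=True)
class PhysicsConfig:
    """RF frequency, permeability, density, and the time-harmonic convention.

    ``time_convention`` fixes the sign of i in the complex admittance
    (sigma + i*omega*eps for ``+iwt``, sigma - i*omega*eps for ``-iwt``).
    SAR depends only on |E| and is invariant to the choice.
    """

    f0: float = 128e6  # Hz
    mu0: float = MU0  # H/m
    rho: float = 1000.0  # kg/m^3
    time_convention: str = "+iwt"

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ConfigError(f"f0 must be positive, got {self.f0}")
        if self.rho <= 0:
            raise ConfigError(f"rho must be positive, got {self.rho}")
        if self.mu0 <= 0:
            raise ConfigError(f"mu0 must be positive, got {self.mu0}")
        if self.time_convention not in ("+iwt", "-iwt"):
            raise ConfigError(f"time_convention must be '+iwt' or '-iwt', got {self.time_convention!r}")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi*f0, rad/s."""
        return 2.0 * math.pi * self.f0


@dataclass(frozen=True)
class ElectricalPropertiesTable:
    """Per-tissue conductivity (S/m) and relative permittivity at f0."""

    sigma: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    eps_r: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_EPSR))

    def __post_init__(self) -> None:
        for code, s in self.sigma.items():
            if s < 0:
                raise ConfigError(f"conductivity for tissue {code} must be >= 0, got {s}")
        for code, e in self.eps_r.items():
            if e < 1:
                raise ConfigError(f"relative permittivity for tissue {code} must be >= 1, got {e}")

    def validate_covers(self, tissue_codes: list[int]) -> None:
        missing = [c for c in tissue_codes if c not in self.sigma or c not in self.eps_r]
        if missing:
            raise ConfigError(f"no electrical properties for tissue codes {missing}")


@dataclass(frozen=True)
class CorrectionFactorTable:
    """Per-tissue multiplicative SAR / 10-g SAR correction factors."""

    sar_factor: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SAR_FACTORS))
    sar10g_factor: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SAR10G_FACTORS))

    def __post_init__(self) -> None:
        for name, table in (("sar_factor", self.sar_factor), ("sar10g_factor", self.sar10g_factor)):
            for code, f in table.items():
                if f < 1:
                    raise ConfigError(f"{name} for tissue {code} must be >= 1, got {f}")

    @classmethod
    def unity(cls) -> "CorrectionFactorTable":
        return cls({c: 1.0 for c in TISSUE_NAMES}, {c: 1.0 for c in TISSUE_NAMES})


@dataclass(frozen=True)
class FilterParams:
    """Kernel sizes and adaptation weights for the reconstruction filters.

    Sizes follow the half-extent convention: the conductivity kernel of size 5
    is a 5x5x5 cuboid (half-extent 2), the postprocessing cube of size 10 is an
    11x11x11 symmetric footprint (half-extent 5), and the gradient ellipsoid of
    size 4 has semi-axes of 4 voxels.
    """

    ept_size: int = 5
    ept_weight: float = 0.05
    post_size: int = 10
    post_weight: float = 0.1
    grad_size: int = 4
    grad_weight: float = 0.05
    gaussian_sigma: float = 0.4  # voxels
    outlier_k: float = 9.0

    def __post_init__(self) -> None:
        if min(self.ept_size, self.post_size, self.grad_size) < 1:
            raise ConfigError("filter sizes must be >= 1")
        if self.gaussian_sigma < 0 or self.outlier_k <= 0:
            raise ConfigError("gaussian_sigma must be >= 0 and outlier_k > 0")


@dataclass(frozen=True)
class EffectiveConfig:
    """The fully resolved configuration actually used by a pipeline run."""

    physics: PhysicsConfig
    properties: ElectricalPropertiesTable
    correction: CorrectionFactorTable
    filters: FilterParams
    pipeline: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "physics": asdict(self.physics),
            "tissues": {
                "sigma": dict(self.properties.sigma),
                "eps_r": dict(self.properties.eps_r),
            },
            "correction": {
                "sar_factor": dict(self.correction.sar_factor),
                "sar10g_factor": dict(self.correction.sar10g_factor),
            },
            "filters": asdict(self.filters),
            "pipeline": dict(self.pipeline),
        }


def default_config() -> EffectiveConfig:
    return EffectiveConfig(
        PhysicsConfig(), ElectricalPropertiesTable(), CorrectionFactorTable(), FilterParams()
    )


def _int_keys(d: dict) -> dict[int, float]:
    out = {}
    for k, v in d.items():
        try:
            code = int(k)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"tissue code {k!r} is not an integer") from exc
        out[code] = float(v)
    return out


def load_config(source: str | Path | dict | None = None) -> EffectiveConfig:
    """Load a YAML config (path, YAML text, dict, or None for pure defaults).

    Defaults are applied for every absent key; the full effective
    configuration is logged at INFO level so a run's provenance is complete.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = yaml.safe_load(io.StringIO(text)) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")

    phys_doc = dict(doc.get("physics", {}))
    physics = PhysicsConfig(
        f0=float(phys_doc.get("f0", 128e6)),
        mu0=float(phys_doc.get("mu0", MU0)),
        rho=float(phys_doc.get("rho", 1000.0)),
        time_convention=str(phys_doc.get("time_convention", "+iwt")),
    )

    tis_doc = dict(doc.get("tissues", {}))
    sigma = dict(DEFAULT_SIGMA)
    sigma.update(_int_keys(tis_doc.get("sigma", {})))
    eps_r = dict(DEFAULT_EPSR)
    eps_r.update(_int_keys(tis_doc.get("eps_r", {})))
    properties = ElectricalPropertiesTable(sigma, eps_r)

    cor_doc = dict(doc.get("correction", {}))
    sar_f = dict(DEFAULT_SAR_FACTORS)
    sar_f.update(_int_keys(cor_doc.get("sar_factor", {})))
    sar10_f = dict(DEFAULT_SAR10G_FACTORS)
    sar10_f.update(_int_keys(cor_doc.get("sar10g_factor", {})))
    correction = CorrectionFactorTable(sar_f, sar10_f)

    filt_doc = dict(doc.get("filters", {}))
    filters = FilterParams(**{k: filt_doc[k] for k in filt_doc})

    cfg = EffectiveConfig(physics, properties, correction, filters, dict(doc.get("pipeline", {})))
    logger.info("effective configuration: %s", cfg.to_dict())
    return cfg


def dump_config(cfg: EffectiveConfig, path: str | Path | None = None) -> str:
    """Serialize the effective configuration; reloading reproduces it exactly."""
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
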