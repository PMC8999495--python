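"""Gray-level to material-property mapping.

An anteroposterior radiograph encodes tissue radiodensity as 8-bit gray
values.  For the plane-elasticity model every pixel needs a Young's modulus
``E`` (MPa) and a Poisson ratio ``nu``.  The mapping is organised as five
tissue classes -- soft tissue, articular cartilage, spongy (trabecular)
bone, compact (cortical) bone and fixation material (implant steel) -- each
owning a contiguous band of gray values and a homogeneous (E, nu) pair:

=============  =========  ==========  ====
class          gray band    E (MPa)    nu
=============  =========  ==========  ====
SOFT_TISSUE      0-49          0.6    0.42
CARTILAGE       50-99        600      0.42
SPONGY_BONE    100-169       3000     0.32
COMPACT_BONE   170-229       5000     0.32
IMPLANT        230-255     210000     0.30
=============  =========  ==========  ====

Two assignment modes exist.  ``DISCRETE`` (default) gives every pixel its
band's homogeneous constants.  ``CONTINUOUS256`` gives each of the 256 gray
levels its own modulus: within a band, log10(E) is interpolated linearly
between edge anchors (geometric means of the E of adjacent classes at
interior band boundaries; the class E itself at the two extreme edges), so
E is continuous and non-decreasing over the full 0-255 range.  E spans six
orders of magnitude, hence the log scale -- linear interpolation would be
dominated entirely by the implant band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Tissue",
    "Radiograph",
    "MaterialBand",
    "MaterialTable",
    "MaterialMap",
    "build_material_table",
    "assign_materials",
    "DEFAULT_BANDS",
]


class Tissue(IntEnum):
    """Tissue classes, ordered by increasing radiodensity."""

    SOFT_TISSUE = 0
    CARTILAGE = 1
    SPONGY_BONE = 2
    COMPACT_BONE = 3
    IMPLANT = 4


#: (gray_lo, gray_hi, class, E_MPa, nu)
DEFAULT_BANDS: tuple[tuple[int, int, Tissue, float, float], ...] = (
    (0, 49, Tissue.SOFT_TISSUE, 0.6, 0.42),
    (50, 99, Tissue.CARTILAGE, 600.0, 0.42),
    (100, 169, Tissue.SPONGY_BONE, 3000.0, 0.32),
    (170, 229, Tissue.COMPACT_BONE, 5000.0, 0.32),
    (230, 255, Tissue.IMPLANT, 210000.0, 0.30),
)


@dataclass(frozen=True)
class Radiograph:
    """8-bit grayscale image with physical pixel spacing.

    Parameters
    ----------
    pixels
        2D uint8 array, row index increasing toward the distal (fixed) end
        of the model.
    pixel_spacing_mm
        Physical edge length of one pixel in mm (default 1.0).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("radiograph must be a 2D image of at least 2x2 pixels")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("gray values must lie in [0, 255]")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class MaterialBand:
    gray_lo: int
    gray_hi: int
    tissue: Tissue
    E_MPa: float
    nu: float

    def __post_init__(self) -> None:
        if not (0 <= self.gray_lo <= self.gray_hi <= 255):
            raise ValueError(f"invalid gray band [{self.gray_lo}, {self.gray_hi}]")
        if not self.E_MPa > 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def center(self) -> int:
        return (self.gray_lo + self.gray_hi) // 2


@dataclass(frozen=True)
class MaterialTable:
    """Ordered, non-overlapping gray bands jointly covering [0, 255]."""

    bands: tuple[MaterialBand, ...]
    mode: str = "discrete"  # "discrete" | "continuous256"

    def __post_init__(self) -> None:
        if self.mode not in ("discrete", "continuous256"):
            raise ValueError(f"unknown mode {self.mode!r}")
        bands = tuple(sorted(self.bands, key=lambda b: b.gray_lo))
        if not bands:
            raise ValueError("material table needs at least one band")
        if bands[0].gray_lo != 0 or bands[-1].gray_hi != 255:
            raise ValueError("bands must jointly cover [0, 255]")
        for a, b in zip(bands, bands[1:]):
            if b.gray_lo <= a.gray_hi:
                raise ValueError(
                    f"bands [{a.gray_lo},{a.gray_hi}] and "
                    f"[{b.gray_lo},{b.gray_hi}] overlap"
                )
            if b.gray_lo != a.gray_hi + 1:
                raise ValueError("bands leave a gap in [0, 255]")
        object.__setattr__(self, "bands", bands)

    # -- lookup -----------------------------------------------------------

    def band_index(self, gray: np.ndarray | int) -> np.ndarray:
        """Index of the band containing each gray value (vectorised)."""
        g = np.asarray(gray)
        if g.size and (g.min() < 0 or g.max() > 255):
            raise ValueError("gray value outside [0, 255]")
        edges = np.array([b.gray_lo for b in self.bands])
        return np.searchsorted(edges, g, side="right") - 1

    def band_of(self, gray: int) -> MaterialBand:
        return self.bands[int(self.band_index(gray))]

    def class_lut(self) -> np.ndarray:
        """(256,) tissue class per gray level."""
        idx = self.band_index(np.arange(256))
        return np.array([self.bands[i].tissue for i in idx], dtype=np.int64)

    def continuous_lut(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-gray-level (E, nu), log-linear E within each band.

        Anchors at interior band boundaries are geometric means of the two
        neighbouring class moduli; at gray 0 and 255 the class modulus is
        used unchanged, so a single-band table degenerates to a constant.
        """
        E = np.empty(256)
        nu = np.empty(256)
        n = len(self.bands)
        for i, b in enumerate(self.bands):
            lo_anchor = (
                float(np.sqrt(self.bands[i - 1].E_MPa * b.E_MPa)) if i > 0 else b.E_MPa
            )
            hi_anchor = (
                float(np.sqrt(b.E_MPa * self.bands[i + 1].E_MPa))
                if i < n - 1
                else b.E_MPa
            )
            g = np.arange(b.gray_lo, b.gray_hi + 1)
            if b.gray_hi == b.gray_lo:
                t = np.zeros(1)
            else:
                t = (g - b.gray_lo) / (b.gray_hi - b.gray_lo)
            logE = np.log10(lo_anchor) + t * (np.log10(hi_anchor) - np.log10(lo_anchor))
            E[g] = 10.0**logE
            nu[g] = b.nu
        return E, nu

    # -- config round trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "bands": [
                {
                    "class": b.tissue.name,
                    "gray_lo": b.gray_lo,
                    "gray_hi": b.gray_hi,
                    "E_MPa": b.E_MPa,
                    "nu": b.nu,
                }
                for b in self.bands
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, cfg: dict) -> "MaterialTable":
        bands = tuple(
            MaterialBand(
                gray_lo=int(b["gray_lo"]),
                gray_hi=int(b["gray_hi"]),
                tissue=Tissue[b["class"]],
                E_MPa=float(b["E_MPa"]),
                nu=float(b["nu"]),
            )
            for b in cfg["bands"]
        )
        return cls(bands=bands, mode=cfg.get("mode", "discrete"))

    @classmethod
    def from_yaml(cls, path) -> "MaterialTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class MaterialMap:
    """Per-pixel material assignment aligned with a source radiograph.

    ``tissue`` always carries the per-pixel class; ``E`` and ``nu`` carry
    the per-pixel constants actually used by the solver (band constants in
    discrete mode, per-gray-level values in continuous mode).
    """

    tissue: np.ndarray  # (H, W) int, Tissue codes
    E: np.ndarray  # (H, W) float, MPa
    nu: np.ndarray  # (H, W) float
    pixel_spacing_mm: float
    table: MaterialTable

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue.shape


def build_material_table(
    config: dict | str | None = None, mode: str = "discrete"
) -> MaterialTable:
    """Build a material table from a config dict / YAML path, or the default.

    The default is the five-class table in the module docstring.
    """
    if config is None:
        return MaterialTable(
            bands=tuple(MaterialBand(lo, hi, t, E, nu) for lo, hi, t, E, nu in DEFAULT_BANDS),
            mode=mode,
        )
    if isinstance(config, (str, bytes)) or hasattr(config, "__fspath__"):
        return MaterialTable.from_yaml(config)
    return MaterialTable.from_dict(config)


def assign_materials(radiograph: Radiograph, table: MaterialTable) -> MaterialMap:
    """Map every pixel of a radiograph to tissue class and (E, nu)."""
    px = radiograph.pixels
    cls_lut = table.class_lut()
    tissue = cls_lut[px]
    if table.mode == "discrete":
        idx = table.band_index(px)
        E_lut = np.array([b.E_MPa for b in table.bands])
        nu_lut = np.array([b.nu for b in table.bands])
        E, nu = E_lut[idx], nu_lut[idx]
    else:
        E_lut, nu_lut = table.continuous_lut()
        E, nu = E_lut[px], nu_lut[px]
    return MaterialMap(
        tissue=tissue,
        E=E,
        nu=nu,
        pixel_spacing_mm=radiograph.pixel_spacing_mm,
        table=table,
    )
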