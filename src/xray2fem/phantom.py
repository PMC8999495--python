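"""Synthetic anteroposterior radiograph phantoms of the proximal femur.

The study cohort this package analyses consists of anteroposterior hip
radiographs of pertrochanteric fractures stabilised with either a gamma
nail (GNF) or a dynamic hip screw (DHS).  Patient images are not available,
so this module renders stylised phantoms with pixel-level ground-truth
tissue labels: a femoral head with an articular cartilage cap, a neck at a
configurable neck-shaft angle, a trochanteric metaphysis, and a shaft with
a compact-bone cortex, spongy interior and soft-tissue medullary canal,
reaching the bottom image edge (the fixed base of the mechanical model).
The cartilage cap touches the top edge so the gravity-axis load applies
directly to the articular surface.

Fracture morphology follows the AO/OTA A-type grades:

* **A1** -- simple oblique gap through the trochanteric region,
* **A2** -- the same oblique plus a lesser-trochanter fragment line
  (multi-fragment), wider gap,
* **A3** -- reverse oblique with an additional wedge fragment line, widest
  gap.

Default gap widths (2/3/4 mm) and the extra fragment lines make the
disrupted-bone area strictly increasing A1 -> A2 -> A3, mirroring the
clinical instability grading.  Gap pixels are labelled SOFT_TISSUE.
Implants are rendered last as filled high-intensity shapes bonded
pixel-wise to bone (no contact mechanics): GNF as an intramedullary nail
with cephalic and distal locking screws, DHS as a lateral plate with a
sliding neck screw and three cortical screws.

Gray values are drawn as band centre +/- uniform jitter (10 gray levels),
which always stays inside the label's default gray band, so discrete-mode
material assignment recovers the ground-truth labels exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image
from scipy import ndimage

from .materials import DEFAULT_BANDS, Radiograph, Tissue

__all__ = [
    "FractureType",
    "Implant",
    "GeometryParams",
    "PhantomSpec",
    "LabelMask",
    "generate_phantom",
    "make_cohort",
    "save_phantom",
]

# reference canvas (mm) the layout constants below are drawn for
_REF_W, _REF_H = 120.0, 220.0

#: gray level rendered at the centre of each tissue's default band
GRAY_CENTERS = {b[2]: (b[0] + b[1]) // 2 for b in DEFAULT_BANDS}
GRAY_JITTER = 10  # +/- uniform, stays within every default band


class FractureType(str, Enum):
    A1 = "A1"
    A2 = "A2"
    A3 = "A3"


class Implant(str, Enum):
    GNF = "GNF"
    DHS = "DHS"
    NONE = "NONE"


_DEFAULT_GAP_MM = {FractureType.A1: 2.0, FractureType.A2: 3.0, FractureType.A3: 4.0}
_DEFAULT_FRAGMENTS = {FractureType.A1: 2, FractureType.A2: 3, FractureType.A3: 3}


@dataclass(frozen=True)
class GeometryParams:
    """Anatomical and implant dimensions in mm (reference-canvas scale)."""

    shaft_width_mm: float = 34.0
    cortex_thickness_mm: float = 6.0
    neck_shaft_angle_deg: float = 130.0
    head_radius_mm: float = 26.0
    cartilage_thickness_mm: float = 4.0
    neck_width_mm: float = 22.0
    canal_width_mm: float = 10.0
    fracture_gap_mm: float | None = None  # None -> per-type default 2/3/4
    fragment_count: int | None = None  # None -> per-type default
    nail_width_mm: float = 9.0
    plate_width_mm: float = 6.0
    screw_width_mm: float = 6.0


@dataclass(frozen=True)
class PhantomSpec:
    fracture_type: FractureType
    implant: Implant = Implant.NONE
    image_height_px: int = 220
    image_width_px: int = 120
    pixel_spacing_mm: float = 1.0
    geometry: GeometryParams = dataclasses.field(default_factory=GeometryParams)
    seed: int = 0

    def __post_init__(self) -> None:
        ftype = FractureType(self.fracture_type)
        implant = Implant(self.implant)
        object.__setattr__(self, "fracture_type", ftype)
        object.__setattr__(self, "implant", implant)
        if self.image_height_px < 64 or self.image_width_px < 64:
            raise ValueError("image must be at least 64 px in each dimension")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel spacing must be positive")
        g = self.geometry
        if not g.cortex_thickness_mm < g.shaft_width_mm / 2:
            raise ValueError("cortex thickness must be below the shaft half-width")
        frags = self.fragment_count
        if ftype is FractureType.A1 and frags > 2:
            raise ValueError("A1 is a simple fracture: fragment count must be 2")
        if ftype in (FractureType.A2, FractureType.A3) and frags < 2:
            raise ValueError("A2/A3 require at least 2 fragments")

    @property
    def gap_mm(self) -> float:
        g = self.geometry.fracture_gap_mm
        return _DEFAULT_GAP_MM[self.fracture_type] if g is None else g

    @property
    def fragment_count(self) -> int:
        f = self.geometry.fragment_count
        return _DEFAULT_FRAGMENTS[self.fracture_type] if f is None else f


@dataclass(frozen=True)
class LabelMask:
    """Ground-truth tissue class per pixel (values are ``Tissue`` codes)."""

    labels: np.ndarray  # (H, W) uint8

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def count(self, tissue: Tissue) -> int:
        return int(np.count_nonzero(self.labels == tissue))


# ---------------------------------------------------------------------------
# geometry predicates on the pixel-centre lattice


def _disk(X, Y, center, radius):
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2


def _thick_segment(X, Y, p0, p1, width):
    """Pixels within ``width/2`` of the segment p0-p1."""
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vx * vx + vy * vy
    t = np.clip(((X - p0[0]) * vx + (Y - p0[1]) * vy) / L2, 0.0, 1.0)
    dx = X - (p0[0] + t * vx)
    dy = Y - (p0[1] + t * vy)
    return dx * dx + dy * dy <= (width / 2) ** 2


def _polygon(X, Y, points):
    path = MplPath(points)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    return path.contains_points(pts).reshape(X.shape)


def _rect(X, Y, x0, x1, y0, y1):
    return (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)


# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[Radiograph, LabelMask]:
    """Render a phantom radiograph and its ground-truth label mask.

    Deterministic: identical specs (including seed) yield bit-identical
    output.  Gray values lie inside the default band of each pixel's label.
    """
    H, W = spec.image_height_px, spec.image_width_px
    sp = spec.pixel_spacing_mm
    g = spec.geometry

    # physical canvas and anisotropic layout scaling from the reference
    cw, ch = W * sp, H * sp
    sx, sy = cw / _REF_W, ch / _REF_H
    s = min(sx, sy)

    def pt(x_ref, y_ref):
        return (x_ref * sx, y_ref * sy)

    rows, cols = np.mgrid[0:H, 0:W]
    X = (cols + 0.5) * sp
    Y = (rows + 0.5) * sp

    shaft_w = g.shaft_width_mm * s
    cortex = g.cortex_thickness_mm * s
    r_head = g.head_radius_mm * s
    cart = g.cartilage_thickness_mm * s
    neck_w = g.neck_width_mm * s
    canal_w = g.canal_width_mm * s
    gap = spec.gap_mm * s

    x_s = 0.65 * cw  # shaft axis
    y_sh = 0.41 * ch  # shaft top / metaphysis bottom
    xm, xl = x_s - shaft_w / 2, x_s + shaft_w / 2  # medial/lateral shaft edges

    # neck axis: rotate the proximal shaft direction (0,-1) toward medial by
    # (180 - neck_shaft_angle); head centre placed so the cartilage cap
    # crosses the top image edge (load surface).
    ang = np.deg2rad(180.0 - g.neck_shaft_angle_deg)
    d = np.array([-np.sin(ang), -np.cos(ang)])
    neck0 = np.array([x_s + 2.0 * sx, 0.265 * ch])
    hc_y = r_head - 2.0 * s
    L_neck = (neck0[1] - hc_y) / -d[1]
    head_c = neck0 + L_neck * d
    if head_c[0] - r_head < -2.0 * s or head_c[0] + r_head > cw:
        raise ValueError("image too small to contain the femur template")

    # --- tissue regions -----------------------------------------------------
    labels = np.full((H, W), Tissue.SOFT_TISSUE, dtype=np.uint8)

    cart_disk = _disk(X, Y, head_c, r_head)
    head_bone = _disk(X, Y, head_c, r_head - cart)
    neck_band = _thick_segment(X, Y, neck0, head_c, neck_w)
    troch = _polygon(
        X,
        Y,
        [
            pt(61, 90.5),
            pt(53, 70),
            pt(64, 52),
            pt(88, 38),
            pt(101, 44),
            pt(99, 75),
            pt(95, 90.5),
        ],
    )
    shaft = _rect(X, Y, xm, xl, y_sh, ch)
    bone = head_bone | neck_band | troch | shaft

    labels[cart_disk] = Tissue.CARTILAGE
    labels[bone] = Tissue.SPONGY_BONE

    cortex_px = max(1, int(round(cortex / sp)))
    shell = bone & ~ndimage.binary_erosion(bone, iterations=cortex_px)
    labels[shell] = Tissue.COMPACT_BONE

    canal = (np.abs(X - x_s) <= canal_w / 2) & (Y >= y_sh + 25 * sy) & bone & ~shell
    labels[canal] = Tissue.SOFT_TISSUE

    # --- fracture gap (overwrites bone, before the implant) -----------------
    for p0, p1, w in _fracture_lines(spec, sx, sy, xm, xl, x_s, gap):
        labels[_thick_segment(X, Y, p0, p1, w)] = Tissue.SOFT_TISSUE

    # --- implant -------------------------------------------------------------
    implant_mask = _implant_mask(spec, X, Y, pt, x_s, xm, xl, head_c, neck0, s, sx, sy)
    if implant_mask is not None:
        labels[implant_mask] = Tissue.IMPLANT

    # --- gray rendering -------------------------------------------------------
    rng = np.random.default_rng(spec.seed)
    jitter = rng.integers(-GRAY_JITTER, GRAY_JITTER + 1, size=(H, W))
    centers = np.zeros(len(Tissue), dtype=np.int64)
    for t in Tissue:
        centers[t] = GRAY_CENTERS[t]
    gray = (centers[labels] + jitter).astype(np.uint8)

    return Radiograph(pixels=gray, pixel_spacing_mm=sp), LabelMask(labels=labels)


def _fracture_lines(spec, sx, sy, xm, xl, x_s, gap):
    """(p0, p1, width) segments carved as soft-tissue gaps.

    Severity is encoded through calcar (medial cortex) continuity, the
    clinical stability criterion: A1 spares it, A2 severs it and detaches
    a lesser-trochanter fragment, A3 is a reverse oblique exiting the
    medial cortex below the trochanter plus a medial wedge line.
    """
    ftype = spec.fracture_type
    lines = []
    if ftype is FractureType.A1:
        # stable simple oblique: starts inside the bone, calcar intact
        lines.append(((xm + 8 * sx, 66 * sy), (xl + 4 * sx, 92 * sy), gap))
    elif ftype is FractureType.A2:
        lines.append(((xm - 10 * sx, 60 * sy), (xl + 4 * sx, 90 * sy), gap))
        # lesser-trochanter (medial) fragment
        lines.append(((xm - 9 * sx, 72 * sy), (x_s - 2 * sx, 97 * sy), gap))
        if spec.fragment_count > 3:
            lines.append(((x_s - 4 * sx, 55 * sy), (xl + 2 * sx, 75 * sy), gap))
    else:  # A3: subtrochanteric reverse oblique + medial wedge
        lines.append(((xl + 5 * sx, 58 * sy), (xm - 8 * sx, 112 * sy), gap))
        lines.append(((xm - 8 * sx, 80 * sy), (x_s, 96 * sy), gap * 1.4))
        if spec.fragment_count > 3:
            lines.append(((xm - 6 * sx, 88 * sy), (x_s + 4 * sx, 74 * sy), gap))
    return lines


def _implant_mask(spec, X, Y, pt, x_s, xm, xl, head_c, neck0, s, sx, sy):
    g = spec.geometry
    screw_w = g.screw_width_mm * s
    if spec.implant is Implant.NONE:
        return None
    if spec.implant is Implant.GNF:
        nail_w = g.nail_width_mm * s
        nail = _rect(X, Y, x_s - nail_w / 2, x_s + nail_w / 2, 42 * sy, 185 * sy)
        anchor = np.array([x_s, 62 * sy])
        u = head_c - anchor
        tip = head_c + 0.25 * g.head_radius_mm * s * u / np.linalg.norm(u)
        neck_screw = _thick_segment(X, Y, anchor, tip, screw_w)
        locking = _rect(X, Y, xm - 3 * sx, xl + 3 * sx, 172 * sy, 176 * sy)
        return nail | neck_screw | locking
    # DHS: lateral plate + sliding neck screw + cortical screws
    plate_w = g.plate_width_mm * s
    plate = _rect(X, Y, xl - 2 * sx, xl - 2 * sx + plate_w, 60 * sy, 185 * sy)
    anchor = np.array([xl, 70 * sy])
    u = head_c - anchor
    tip = head_c + 0.25 * g.head_radius_mm * s * u / np.linalg.norm(u)
    neck_screw = _thick_segment(X, Y, anchor, tip, screw_w * 1.15)
    screws = np.zeros_like(plate)
    for y0 in (108, 133, 158):
        screws |= _rect(X, Y, xm - 3 * sx, xl - 2 * sx + plate_w, y0 * sy, (y0 + 3) * sy)
    return plate | neck_screw | screws


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    n_per_cell: int,
    types: list[FractureType] | None = None,
    implants: list[Implant] | None = None,
    base_seed: int = 0,
    image_height_px: int = 220,
    image_width_px: int = 120,
    pixel_spacing_mm: float = 1.0,
) -> list[PhantomSpec]:
    """Deterministic factorial cohort of phantom specs.

    One geometry jitter draw (shaft width, neck-shaft angle, head radius,
    gap scale) is made per replicate index and shared across all fracture
    type x implant cells of that replicate, so matched replicates differ
    only in fracture morphology and hardware.  Per-spec gray-noise seeds
    are derived reproducibly from ``base_seed``.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    types = (
        [FractureType.A1, FractureType.A2, FractureType.A3]
        if types is None
        else list(types)
    )
    implants = [Implant.GNF, Implant.DHS] if implants is None else list(implants)
    if not types or not implants:
        raise ValueError("types and implants must be non-empty")

    specs: list[PhantomSpec] = []
    for i in range(n_per_cell):
        jit = np.random.default_rng([int(base_seed) & 0x7FFFFFFF, 17, i])
        shaft = 34.0 + jit.uniform(-2, 2)
        angle = 130.0 + jit.uniform(-4, 4)
        r_head = 26.0 + jit.uniform(-2, 2)
        gap_scale = jit.uniform(0.9, 1.1)
        for t_idx, ftype in enumerate(types):
            ftype = FractureType(ftype)
            for m_idx, imp in enumerate(implants):
                seed = int(
                    np.random.SeedSequence(
                        [int(base_seed) & 0x7FFFFFFF, i, t_idx, m_idx]
                    ).generate_state(1)[0]
                    % (2**31)
                )
                geom = GeometryParams(
                    shaft_width_mm=shaft,
                    neck_shaft_angle_deg=angle,
                    head_radius_mm=r_head,
                    fracture_gap_mm=_DEFAULT_GAP_MM[ftype] * gap_scale,
                )
                specs.append(
                    PhantomSpec(
                        fracture_type=ftype,
                        implant=Implant(imp),
                        image_height_px=image_height_px,
                        image_width_px=image_width_px,
                        pixel_spacing_mm=pixel_spacing_mm,
                        geometry=geom,
                        seed=seed,
                    )
                )
    return specs


def save_phantom(radiograph: Radiograph, mask: LabelMask, out_dir, stem: str) -> None:
    """Write the image and mask as 8-bit grayscale PNGs.

    The mask PNG stores raw ``Tissue`` codes 0-4 (SOFT_TISSUE=0,
    CARTILAGE=1, SPONGY_BONE=2, COMPACT_BONE=3, IMPLANT=4).
    """
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(radiograph.pixels, mode="L").save(out / f"{stem}.png")
    Image.fromarray(mask.labels, mode="L").save(out / f"{stem}_mask.png")
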