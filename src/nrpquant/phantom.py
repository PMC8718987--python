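"""Synthetic membrane phantoms with exact ground truth.

Real NRP membranes cannot ship with the package, so every analysis stage is
exercised against synthetic phantoms that emulate the two experimental
designs the method is validated on:

* **dot blot**: a pipetting grid of spots whose amplitude follows a known
  dose-response over a graded concentration series (default: ten levels,
  0.01-0.1 M, six replicates each — the standard validation layout), with
  multiplicative replicate noise (lognormal, parameterized by CV), additive
  pixel noise, and a smooth background plane;
* **brain print**: a bilaterally mirror-symmetric slice print with a
  radially decaying unilateral lesion (multiplicative suppression
  w(p) = 1 - depth * exp(-||p - c||^2 / (2 sigma^2)) applied to one
  hemisphere only), emulating probe-placement trauma.

Spots are flat disks with a 2-px cosine-taper rim. The taper has compact
support, so each spot's exact integrated density is computable and fully
captured by a measurement disk of radius ``spot_radius + rim_width`` —
ground truth and pipeline readout agree to floating precision on noiseless
phantoms. Identical spec + seed reproduces every output byte-for-byte, and
pixel values never leave [0, 1] (clipping is flagged when it occurs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, GeometryError
from .image_io import MembraneImage
from .spatial import RegionOfInterest

__all__ = [
    "DotBlotSpec",
    "BrainPhantomSpec",
    "BrainPhantom",
    "make_dotblot",
    "make_oxidation_pair",
    "make_brain_phantom",
]

#: rim width of the spot taper, px
RIM_WIDTH = 2.0


def _amplitude(response, c: float) -> float:
    """Dose-response amplitude A(c) for a nominal concentration c (mol/L)."""
    kind = response[0]
    if kind == "linear":
        return response[1] * c
    if kind == "saturating":
        a_max, k = response[1], response[2]
        return a_max * (1.0 - np.exp(-k * c))
    raise DataError(f"unknown response kind {kind!r}")


def _spot_stamp(shape, center, radius, rim=RIM_WIDTH):
    """Unit-amplitude spot: flat disk with a cosine taper over [radius, radius+rim]."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    d = np.hypot(rows - center[0], cols - center[1])
    stamp = np.zeros(shape)
    stamp[d <= radius] = 1.0
    rimzone = (d > radius) & (d < radius + rim)
    stamp[rimzone] = 0.5 * (1.0 + np.cos(np.pi * (d[rimzone] - radius) / rim))
    return stamp


@dataclass(frozen=True)
class DotBlotSpec:
    """Design of a synthetic dot-blot membrane.

    One concentration level per grid row, one replicate per column. The
    default series mirrors the standard validation design: ten levels from
    0.01 to 0.1 M, six replicates, 5% replicate CV.
    """

    levels: tuple[float, ...] = tuple(np.round(np.linspace(0.01, 0.1, 10), 3))
    replicates: int = 6
    spot_radius: float = 6.0
    spacing: float = 32.0
    margin: float = 20.0
    response: tuple = ("linear", 8.0)  # ("linear", slope) or ("saturating", A_max, k)
    replicate_cv: float = 0.05
    pixel_noise: float = 0.01
    background: tuple[float, float, float] = (0.03, 5e-5, 5e-5)  # b0 + br*row + bc*col
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.levels):
            raise DataError("concentrations must be > 0")
        if self.spacing < 2 * (self.spot_radius + RIM_WIDTH):
            raise GeometryError("grid spacing too small for the spot radius")
        if self.margin < self.spot_radius + RIM_WIDTH:
            raise GeometryError("margin too small for the spot radius")

    @property
    def roi_radius(self) -> float:
        """Measurement radius that captures a spot's full (compact) footprint."""
        return self.spot_radius + RIM_WIDTH

    @property
    def canvas_shape(self) -> tuple[int, int]:
        h = int(round(2 * self.margin + (len(self.levels) - 1) * self.spacing)) + 1
        w = int(round(2 * self.margin + (self.replicates - 1) * self.spacing)) + 1
        return h, w


def make_dotblot(spec: DotBlotSpec) -> tuple[MembraneImage, pd.DataFrame]:
    """Render a dot-blot phantom and its ground-truth table.

    Returns the reductive-scale image and a truth table with one row per
    spot: label, level index, nominal concentration, spot center, the
    measurement ROI radius, the realized amplitude (dose-response times the
    lognormal replicate factor), and the exact noiseless integrated density.
    Table ``attrs`` carry the unit-stamp integral and, for a linear
    response, the implied integrated-density slope.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.canvas_shape
    b0, br, bc = spec.background
    rows_idx = np.arange(shape[0])[:, None]
    cols_idx = np.arange(shape[1])[None, :]
    canvas = np.broadcast_to(
        float(b0) + float(br) * rows_idx + float(bc) * cols_idx, shape
    ).astype(np.float64)

    if spec.replicate_cv > 0:
        sigma_ln = np.sqrt(np.log(1.0 + spec.replicate_cv**2))
        mu_ln = -0.5 * sigma_ln**2
    rows = []
    unit_sum = None
    for i, c in enumerate(spec.levels):
        for j in range(spec.replicates):
            center = (spec.margin + i * spec.spacing, spec.margin + j * spec.spacing)
            factor = (float(rng.lognormal(mu_ln, sigma_ln))
                      if spec.replicate_cv > 0 else 1.0)
            amp = _amplitude(spec.response, c) * factor
            stamp = _spot_stamp(shape, center, spec.spot_radius)
            if unit_sum is None:
                unit_sum = float(stamp.sum())
            canvas += amp * stamp
            rows.append({
                "label": f"L{i + 1:02d}R{j + 1}",
                "level_index": i,
                "nominal": c,
                "replicate": j + 1,
                "row": center[0],
                "col": center[1],
                "roi_radius": spec.roi_radius,
                "amplitude": amp,
                "true_integrated_density": amp * unit_sum,
            })

    if spec.pixel_noise > 0:
        canvas = canvas + rng.normal(0.0, spec.pixel_noise, size=shape)

    clipped = bool(canvas.min() < 0 or canvas.max() > 1)
    canvas = np.clip(canvas, 0.0, 1.0)

    truth = pd.DataFrame(rows)
    truth.attrs["unit_stamp_sum"] = unit_sum
    truth.attrs["clipped"] = clipped
    if spec.response[0] == "linear":
        truth.attrs["density_slope"] = spec.response[1] * unit_sum
    img = MembraneImage(pixels=canvas, scale_note=f"dotblot phantom seed={spec.seed}",
                        is_reductive_scale=True)
    return img, truth


def make_oxidation_pair(
    base_concentration: float = 0.05,
    oxidized_fraction: float = 0.4,
    replicates: int = 6,
    replicate_cv: float = 0.05,
    pixel_noise: float = 0.01,
    seed: int = 0,
    response: tuple = ("linear", 8.0),
) -> tuple[MembraneImage, MembraneImage, pd.DataFrame]:
    """Paired membranes of isoconcentrated aliquots, one arm physically oxidized.

    Untreated aliquots respond at A(c); treated aliquots at
    A(c * (1 - oxidized_fraction)), i.e. oxidation removes a fraction of the
    reductive capacity without changing the nominal concentration. Returns
    (untreated image, treated image, truth table with paired labels).
    """
    if not (0.0 <= oxidized_fraction <= 1.0):
        raise DataError("oxidized_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    images = []
    for arm, conc in (("untreated", base_concentration),
                      ("treated", base_concentration * (1.0 - oxidized_fraction))):
        arm_seed = int(rng.integers(0, 2**31 - 1))
        spec = DotBlotSpec(levels=(max(conc, 1e-12),), replicates=replicates,
                           replicate_cv=replicate_cv, pixel_noise=pixel_noise,
                           response=response, seed=arm_seed)
        img, truth = make_dotblot(spec)
        truth = truth.assign(arm=arm, pair_id=truth["replicate"],
                             label=[f"{arm}_{k + 1}" for k in range(len(truth))])
        frames.append(truth)
        images.append(img)
    truth = pd.concat(frames, ignore_index=True)
    return images[0], images[1], truth


@dataclass(frozen=True)
class BrainPhantomSpec:
    """Design of a bilaterally symmetric brain-print phantom with one lesion.

    The pre-lesion field is built from mirrored elliptical structures
    evaluated as functions of (row, |col - midline|), which makes it exactly
    mirror-symmetric by construction. The lesion multiplies one hemisphere
    by w(p) = 1 - depth * exp(-||p - center||^2 / (2 sigma^2)).
    """

    height: int = 220
    width: int = 320
    midline_col: int | None = None  # default: width // 2
    background: float = 0.05
    brain_intensity: float = 0.55
    lesion_center: tuple[float, float] = (80.0, 205.0)  # source coords, ipsi side
    lesion_depth: float = 0.3
    lesion_sigma: float = 30.0
    lesion_side: str = "right"
    pixel_noise: float = 0.01
    n_rois: int = 6
    roi_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lesion_depth <= 1.0):
            raise DataError("lesion_depth must be in [0, 1]")
        if self.lesion_side not in ("left", "right"):
            raise DataError("lesion_side must be 'left' or 'right'")

    @property
    def midline(self) -> int:
        return self.width // 2 if self.midline_col is None else self.midline_col


@dataclass(frozen=True)
class BrainPhantom:
    """A brain-print phantom bundle: image, truth fields, ROIs, trauma point."""

    image: MembraneImage            # lesioned, noisy
    pre_lesion: MembraneImage       # noiseless, exactly mirror-symmetric
    lesion_weight: np.ndarray       # multiplicative field; 1 where untouched
    rois: tuple[RegionOfInterest, ...]
    trauma: tuple[float, float]
    midline_col: int
    ipsilateral_side: str
    clipped: bool


# mirrored detail structures: (center_row, |col-m| offset, row_radius, col_radius, delta)
_DETAIL_ELLIPSES = (
    (40.0, 60.0, 18.0, 50.0, 0.15),
    (190.0, 100.0, 15.0, 25.0, 0.12),
)


def _symmetric_field(spec: BrainPhantomSpec) -> np.ndarray:
    h, w, m = spec.height, spec.width, spec.midline
    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)
    dcol = np.abs(cols - m)  # symmetric coordinate
    field = np.full((h, w), spec.background)

    # hemisphere-spanning brain ellipse, symmetric about the midline
    cr, r_r, r_c = h / 2.0, 0.43 * h, 0.45 * w
    inside = ((rows - cr) / r_r) ** 2 + (dcol / r_c) ** 2 <= 1.0
    field[inside] += spec.brain_intensity

    for er, ed, rr, rc, delta in _DETAIL_ELLIPSES:
        e = ((rows - er) / rr) ** 2 + ((dcol - ed) / rc) ** 2 <= 1.0
        field[e] += delta
    return np.clip(field, 0.0, 1.0)


def _roi_squares(spec: BrainPhantomSpec) -> tuple[RegionOfInterest, ...]:
    """Square ROIs on the ipsilateral side at graded distances from the trauma."""
    tr, tc = spec.lesion_center
    # march ventrally and slightly medially, staying inside the brain ellipse
    direction = np.array([0.98, -0.20])
    if spec.lesion_side == "left":
        direction[1] = -direction[1]
    half = spec.roi_size // 2
    rois = []
    for k in range(spec.n_rois):
        dist = 12.0 + 20.0 * k
        cr = tr + dist * direction[0]
        cc = tc + dist * direction[1]
        poly = ((cr - half, cc - half), (cr - half, cc + half),
                (cr + half, cc + half), (cr + half, cc - half))
        rois.append(RegionOfInterest(name=f"roi_{k + 1:02d}", polygon=poly))
    return tuple(rois)


def make_brain_phantom(spec: BrainPhantomSpec) -> BrainPhantom:
    """Render the lesioned brain print plus every ground-truth field.

    Returns the noisy lesioned image, the noiseless pre-lesion image (exactly
    mirror-symmetric), the multiplicative lesion weight field, the graded-
    distance ROI set, and the trauma coordinates. With ``lesion_depth=0`` the
    output is symmetric up to pixel noise and the bilateral difference map of
    the noiseless image is identically zero.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, m = spec.height, spec.width, spec.midline
    pre = _symmetric_field(spec)

    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)
    tr, tc = spec.lesion_center
    g = np.exp(-((rows - tr) ** 2 + (cols - tc) ** 2) / (2.0 * spec.lesion_sigma**2))
    weight = 1.0 - spec.lesion_depth * g
    side_mask = cols > m if spec.lesion_side == "right" else cols < m
    lesion_weight = np.where(side_mask, weight, 1.0)

    lesioned = pre * lesion_weight
    if spec.pixel_noise > 0:
        lesioned = lesioned + rng.normal(0.0, spec.pixel_noise, size=(h, w))
    clipped = bool(lesioned.min() < 0 or lesioned.max() > 1)
    lesioned = np.clip(lesioned, 0.0, 1.0)

    return BrainPhantom(
        image=MembraneImage(lesioned, scale_note=f"brain phantom seed={spec.seed}",
                            is_reductive_scale=True),
        pre_lesion=MembraneImage(pre, scale_note="brain phantom, pre-lesion truth",
                                 is_reductive_scale=True),
        lesion_weight=lesion_weight,
        rois=_roi_squares(spec),
        trauma=spec.lesion_center,
        midline_col=m,
        ipsilateral_side=spec.lesion_side,
        clipped=clipped,
    )
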