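"""Synthetic TTC-phantom cohorts: images, masks, masses and exact truth.

The generator emulates the structure of a porcine ischemia/reperfusion
infarct-staining study: each heart is cut into 5–7 transverse slices
(10–20 mm), both cut surfaces of each slice are photographed — the two
outermost surfaces of the stack are not cut faces and are not imaged — and
every slice is weighed.  On each face the left ventricle appears as a
perturbed annulus; the area at risk (AAR) is an angular sector of it, the
infarct a predominantly subendocardial sub-region of the AAR, and the right
ventricle a tapered crescent appended to the LV wall.  Coloration follows
TTC staining (brick-red remote, light-red viable AAR, white infarct) with
per-face color jitter, an illumination gradient, pixel noise and blur.

Cohort-level parameters reproduce the ranges of the emulated study: infarct
size 0–73% of the AAR, AAR 9–38% of the left ventricle, with a configurable
fraction of "protected" experiments drawn from a low-IS regime.  Requested
per-face class fractions are realized by rank thresholding on smooth scalar
fields, so the rendered pixel shares match the continuous truth up to
rasterization.  The generator doubles as the oracle for the quantification
path: :func:`true_is` evaluates the same mass-normalization formula on the
continuous geometry instead of pixels.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import ExperimentRecord, SliceRecord
from .quantify import ISResult, infarct_size, slice_class_masses
from .scheme import (INFARCT, NON_INFARCTED_AAR, REMAINING, REMOTE,
                     RIGHT_VENTRICLE)

__all__ = [
    "PhantomConfig",
    "TissuePalette",
    "FaceGeometry",
    "GroundTruth",
    "generate_cohort",
    "render_slice_face",
    "true_is",
    "ConfigError",
]

#: myocardial density, g/mm^3
_DENSITY = 1.05e-3


class ConfigError(ValueError):
    """A phantom configuration field violates its invariant."""


@dataclasses.dataclass
class TissuePalette:
    """Mean RGB and jitter SD per rendered tissue, 0–255 scale."""

    background: tuple = (45.0, 40.0, 50.0)
    lumen: tuple = (38.0, 30.0, 34.0)
    remote: tuple = (148.0, 48.0, 42.0)
    non_infarcted_aar: tuple = (225.0, 128.0, 112.0)
    infarct: tuple = (246.0, 240.0, 228.0)
    right_ventricle: tuple = (180.0, 85.0, 75.0)
    jitter_sd: float = 6.0
    pixel_noise_sd: float = 4.0

    def degraded(self, strength: float = 0.5) -> "TissuePalette":
        """Contrast-compressed variant (emulates weaker staining contrast)."""
        names = ["remote", "non_infarcted_aar", "infarct", "right_ventricle"]
        colors = np.array([getattr(self, n) for n in names], dtype=float)
        mean = colors.mean(axis=0)
        shrunk = mean + (colors - mean) * (1.0 - strength)
        kw = {n: tuple(c) for n, c in zip(names, shrunk)}
        return dataclasses.replace(
            self, jitter_sd=self.jitter_sd * 1.5, **kw
        )


@dataclasses.dataclass
class PhantomConfig:
    """Study conditions for one synthetic cohort."""

    n_experiments: int = 24
    protection_fraction: float = 0.415
    slices_per_heart: tuple[int, int] = (5, 7)
    slice_thickness_mm: tuple[float, float] = (10.0, 20.0)
    aar_lv_fraction: tuple[float, float] = (0.09, 0.38)
    is_aar_fraction: tuple[float, float] = (0.0, 0.73)
    image_size: int = 384
    palette: TissuePalette = dataclasses.field(default_factory=TissuePalette)
    illumination_jitter: tuple[float, float] = (0.0, 0.12)
    blur_sigma: tuple[float, float] = (0.3, 0.9)
    species_profile: str = "pig"
    degraded_contrast: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.species_profile not in ("pig", "rat"):
            raise ConfigError(
                f"species_profile must be 'pig' or 'rat', got {self.species_profile!r}"
            )
        if self.species_profile == "rat":
            # isolated rat hearts: thinner slices, fewer of them, smaller extent
            if self.slices_per_heart == (5, 7):
                self.slices_per_heart = (5, 6)
            if self.slice_thickness_mm == (10.0, 20.0):
                self.slice_thickness_mm = (1.8, 2.4)
        for name in ("slices_per_heart", "slice_thickness_mm",
                     "aar_lv_fraction", "is_aar_fraction",
                     "illumination_jitter", "blur_sigma"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        for name in ("aar_lv_fraction", "is_aar_fraction", "protection_fraction"):
            val = getattr(self, name)
            vals = val if isinstance(val, tuple) else (val,)
            if any(v < 0 or v > 1 for v in vals):
                raise ConfigError(f"{name}: fractions must lie in [0, 1], got {val}")
        if self.n_experiments < 1:
            raise ConfigError(f"n_experiments must be >= 1, got {self.n_experiments}")
        if self.image_size < 64:
            raise ConfigError(f"image_size must be >= 64, got {self.image_size}")
        if self.slices_per_heart[0] < 1:
            raise ConfigError("slices_per_heart: need at least one slice")
        if self.slice_thickness_mm[0] <= 0:
            raise ConfigError("slice_thickness_mm: thickness must be positive")

    @property
    def physical_extent_mm(self) -> float:
        """Physical width of the imaged field (sets the px→mm scale)."""
        return 110.0 if self.species_profile == "pig" else 22.0


@dataclasses.dataclass
class FaceGeometry:
    """Continuous parameters of one rendered cut face."""

    cx: float                   # center, fraction of image size
    cy: float
    r_outer: float              # outer LV radius, fraction of image size
    r_inner_ratio: float        # lumen radius / outer radius
    wall_amps: np.ndarray       # Fourier amplitudes of the wall perturbation
    wall_phases: np.ndarray
    aar_angle: float            # AAR sector center, radians
    aar_fraction: float         # AAR area fraction of the LV annulus
    infarct_fraction: float     # infarct area fraction of the AAR
    infarct_amps: np.ndarray    # wavy infarct-border field
    infarct_phases: np.ndarray
    rv_angle: float
    rv_halfwidth: float         # radians
    rv_thickness: float         # crescent peak thickness / r_outer

    def lv_area_px(self, image_size: int) -> float:
        """Analytic LV annulus area in px² (perturbations average out)."""
        r_out = self.r_outer * image_size
        return math.pi * r_out**2 * (1.0 - self.r_inner_ratio**2)

    def rv_area_px(self, image_size: int) -> float:
        """Analytic crescent area: ∫ R²·T·cos²(πΔ/2h) dθ ≈ R²·T·h."""
        r_out = self.r_outer * image_size
        return r_out**2 * self.rv_thickness * self.rv_halfwidth

    def class_fractions(self) -> tuple[float, float, float]:
        """(infarct, non-infarcted AAR, remote) as fractions of the LV."""
        f_inf = self.aar_fraction * self.infarct_fraction
        f_aarni = self.aar_fraction * (1.0 - self.infarct_fraction)
        return f_inf, f_aarni, 1.0 - f_inf - f_aarni


@dataclasses.dataclass
class GroundTruth:
    """Generator-side oracle: exact IS/AAR plus the continuous geometry."""

    is_pct_aar: dict[str, float] = dataclasses.field(default_factory=dict)
    aar_pct_lv: dict[str, float] = dataclasses.field(default_factory=dict)
    results: dict[str, ISResult] = dataclasses.field(default_factory=dict)
    # (experiment_id, slice_index, face) -> FaceGeometry, imaged faces only
    face_geometry: dict = dataclasses.field(default_factory=dict)
    groups: dict[str, str] = dataclasses.field(default_factory=dict)


def _rank_threshold(values: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean selector of the ``round(fraction·n)`` smallest entries."""
    n = values.size
    k = int(round(fraction * n))
    sel = np.zeros(n, dtype=bool)
    if k <= 0:
        return sel
    if k >= n:
        return ~sel
    idx = np.argpartition(values, k - 1)[:k]
    sel[idx] = True
    return sel


def _fourier(theta: np.ndarray, amps: np.ndarray, phases: np.ndarray,
             k0: int = 2) -> np.ndarray:
    out = np.zeros_like(theta)
    for i, (a, p) in enumerate(zip(amps, phases)):
        out += a * np.cos((k0 + i) * theta + p)
    return out


def render_slice_face(
    geom: FaceGeometry,
    palette: TissuePalette,
    rng: np.random.Generator,
    image_size: int = 384,
    illumination: float = 0.0,
    blur_sigma: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one cut face into an RGB image and its 5-class label mask.

    Returns ``(image, mask)`` of identical spatial dimensions; the rendered
    per-class pixel shares match the geometry's continuous fractions up to
    rasterization (rank thresholding on smooth fields realizes them).
    """
    if image_size < 64:
        raise ValueError(f"image_size must be >= 64, got {image_size}")
    size = image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx = xx / size - geom.cx
    dy = yy / size - geom.cy
    rr = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    r_out = geom.r_outer * (1.0 + _fourier(theta, geom.wall_amps, geom.wall_phases))
    r_in = r_out * geom.r_inner_ratio

    lv = (rr >= r_in) & (rr <= r_out)
    if not lv.any():
        raise ValueError("degenerate geometry: zero LV area")
    lumen = rr < r_in

    # tapered RV crescent appended to the outer wall
    d_rv = np.angle(np.exp(1j * (theta - geom.rv_angle)))
    taper = np.cos(np.pi * d_rv / (2.0 * geom.rv_halfwidth)) ** 2
    taper[np.abs(d_rv) >= geom.rv_halfwidth] = 0.0
    rv = (rr > r_out) & (rr <= r_out * (1.0 + geom.rv_thickness * taper))

    mask = np.full((size, size), REMAINING, dtype=np.uint8)
    mask[lv] = REMOTE
    mask[rv] = RIGHT_VENTRICLE

    # AAR: angular sector selected by rank so its LV share is exact
    lv_idx = np.flatnonzero(lv.ravel())
    d_aar = np.abs(np.angle(np.exp(1j * (theta.ravel()[lv_idx] - geom.aar_angle))))
    aar_sel = _rank_threshold(d_aar, geom.aar_fraction)
    aar_idx = lv_idx[aar_sel]
    mask.ravel()[aar_idx] = NON_INFARCTED_AAR

    # infarct: subendocardial sub-region with a wavy border, exact AAR share
    if aar_idx.size:
        u = (rr.ravel()[aar_idx] - r_in.ravel()[aar_idx]) / np.maximum(
            r_out.ravel()[aar_idx] - r_in.ravel()[aar_idx], 1e-9
        )
        wave = _fourier(theta.ravel()[aar_idx], geom.infarct_amps,
                        geom.infarct_phases, k0=3)
        inf_sel = _rank_threshold(u + wave, geom.infarct_fraction)
        mask.ravel()[aar_idx[inf_sel]] = INFARCT

    # ---- coloration -------------------------------------------------------
    jit = palette.jitter_sd
    colors = {
        REMAINING: np.asarray(palette.background, dtype=float),
        REMOTE: np.asarray(palette.remote) + rng.normal(0, jit, 3),
        NON_INFARCTED_AAR: np.asarray(palette.non_infarcted_aar) + rng.normal(0, jit, 3),
        INFARCT: np.asarray(palette.infarct) + rng.normal(0, jit, 3),
        RIGHT_VENTRICLE: np.asarray(palette.right_ventricle) + rng.normal(0, jit, 3),
    }
    img = np.empty((size, size, 3), dtype=np.float64)
    for cls, col in colors.items():
        img[mask == cls] = col
    img[lumen] = np.asarray(palette.lumen, dtype=float)

    if illumination != 0.0:
        phi = rng.uniform(0, 2 * math.pi)
        ramp = 1.0 + illumination * (
            np.cos(phi) * (xx / size - 0.5) + np.sin(phi) * (yy / size - 0.5)
        ) * 2.0
        img *= ramp[..., None]
    img += rng.normal(0.0, palette.pixel_noise_sd, img.shape)
    if blur_sigma > 0:
        img = gaussian_filter(img, sigma=(blur_sigma, blur_sigma, 0))
    return np.clip(img, 0, 255).astype(np.uint8), mask


def _sample_face_geometry(rng: np.random.Generator, base: dict,
                          config: PhantomConfig) -> FaceGeometry:
    """Perturb slice-level geometry into one face's parameters."""
    lo_a, hi_a = config.aar_lv_fraction
    lo_i, hi_i = config.is_aar_fraction
    return FaceGeometry(
        cx=base["cx"] + rng.normal(0, 0.004),
        cy=base["cy"] + rng.normal(0, 0.004),
        r_outer=base["r_outer"] * (1.0 + rng.normal(0, 0.015)),
        r_inner_ratio=np.clip(base["r_inner_ratio"] + rng.normal(0, 0.01), 0.3, 0.6),
        wall_amps=base["wall_amps"] + rng.normal(0, 0.003, base["wall_amps"].size),
        wall_phases=base["wall_phases"],
        aar_angle=base["aar_angle"] + rng.normal(0, 0.03),
        aar_fraction=float(np.clip(base["aar_fraction"] + rng.normal(0, 0.012),
                                   lo_a, hi_a)),
        infarct_fraction=float(np.clip(base["infarct_fraction"] + rng.normal(0, 0.015),
                                       lo_i, hi_i)),
        infarct_amps=base["infarct_amps"],
        infarct_phases=base["infarct_phases"],
        rv_angle=base["rv_angle"],
        rv_halfwidth=base["rv_halfwidth"],
        rv_thickness=base["rv_thickness"],
    )


def generate_cohort(
    config: PhantomConfig,
) -> tuple[list[ExperimentRecord], GroundTruth]:
    """Generate a reproducible phantom cohort with exact ground truth.

    The two outermost surfaces of each heart (apical face of slice 1, basal
    face of the last slice) are not cut surfaces and receive no image, so a
    heart with n slices yields ``2n − 2`` face images.  Identical config and
    seed reproduce the cohort bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    palette = config.palette.degraded() if config.degraded_contrast else config.palette

    n = config.n_experiments
    n_prot = int(round(config.protection_fraction * n))
    groups = np.array(["IR_protected"] * n_prot + ["IR"] * (n - n_prot))
    rng.shuffle(groups)

    lo_a, hi_a = config.aar_lv_fraction
    lo_i, hi_i = config.is_aar_fraction
    span_i = hi_i - lo_i
    mm_per_px = config.physical_extent_mm / config.image_size

    experiments: list[ExperimentRecord] = []
    gt = GroundTruth()
    width = len(str(n))
    for e in range(n):
        exp_id = f"E{e + 1:0{width}d}"
        group = str(groups[e])
        n_slices = int(rng.integers(config.slices_per_heart[0],
                                    config.slices_per_heart[1] + 1))
        heart_aar = rng.uniform(lo_a, hi_a)
        if group == "IR_protected":
            heart_is = rng.uniform(lo_i, lo_i + 0.35 * span_i)
        else:
            heart_is = rng.uniform(lo_i, hi_i)
        heart = {
            "cx": rng.uniform(0.46, 0.54),
            "cy": rng.uniform(0.46, 0.54),
            "r_outer": rng.uniform(0.30, 0.37),
            "r_inner_ratio": rng.uniform(0.40, 0.50),
            "aar_angle": rng.uniform(0, 2 * math.pi),
            "rv_halfwidth": rng.uniform(0.9, 1.3),
            "rv_thickness": rng.uniform(0.25, 0.45),
        }
        heart["rv_angle"] = heart["aar_angle"] + rng.uniform(2.0, 4.0)

        slices: list[SliceRecord] = []
        slice_truth = []   # (mass_g, [(A_lv_px, f_inf, f_aarni, f_rem)] per imaged face)
        for s in range(1, n_slices + 1):
            pos = (s - 1) / max(n_slices - 1, 1)   # 0 at apex, 1 at base
            base = dict(heart)
            base["r_outer"] = heart["r_outer"] * (0.78 + 0.32 * pos)
            base["aar_fraction"] = float(np.clip(
                heart_aar + 0.06 * (0.5 - pos) + rng.normal(0, 0.02), lo_a, hi_a))
            base["infarct_fraction"] = float(np.clip(
                heart_is + rng.normal(0, 0.04 * max(span_i, 1e-9)), lo_i, hi_i))
            base["wall_amps"] = rng.normal(0, 0.02, 3)
            base["wall_phases"] = rng.uniform(0, 2 * math.pi, 3)
            base["infarct_amps"] = rng.normal(0, 0.12, 4)
            base["infarct_phases"] = rng.uniform(0, 2 * math.pi, 4)

            geom_ap = _sample_face_geometry(rng, base, config)
            geom_ba = _sample_face_geometry(rng, base, config)
            thickness = rng.uniform(*config.slice_thickness_mm)

            # weighed mass from the mean physical cross-section of both
            # physical faces (imaged or not)
            area_mm2 = np.mean([
                (g.lv_area_px(config.image_size) + g.rv_area_px(config.image_size))
                * mm_per_px**2
                for g in (geom_ap, geom_ba)
            ])
            mass_g = float(_DENSITY * thickness * area_mm2)

            rec = SliceRecord(slice_index=s, mass_g=mass_g)
            truth_faces = []
            for face, geom in (("apical", geom_ap), ("basal", geom_ba)):
                is_outermost = (face == "apical" and s == 1) or (
                    face == "basal" and s == n_slices)
                if is_outermost:
                    continue
                illum = rng.uniform(*config.illumination_jitter)
                sigma = rng.uniform(*config.blur_sigma)
                img, mask = render_slice_face(
                    geom, palette, rng, config.image_size,
                    illumination=illum, blur_sigma=sigma,
                )
                setattr(rec, f"{face}_image", img)
                setattr(rec, f"{face}_mask", mask)
                gt.face_geometry[(exp_id, s, face)] = geom
                f_inf, f_aarni, f_rem = geom.class_fractions()
                truth_faces.append(
                    (geom.lv_area_px(config.image_size), f_inf, f_aarni, f_rem)
                )
            slices.append(rec)
            slice_truth.append((mass_g, truth_faces))

        experiments.append(
            ExperimentRecord(experiment_id=exp_id, group=group, slices=slices)
        )
        result = _truth_from_fractions(slice_truth)
        gt.results[exp_id] = result
        gt.is_pct_aar[exp_id] = result.is_pct_aar
        gt.aar_pct_lv[exp_id] = result.aar_pct_lv
        gt.groups[exp_id] = group
    return experiments, gt


def _truth_from_fractions(slice_truth) -> ISResult:
    """Evaluate the quantification formula on continuous face fractions."""
    per_slice = []
    for idx, (mass_g, faces) in enumerate(slice_truth, start=1):
        face_area_vecs = []
        for a_lv, f_inf, f_aarni, f_rem in faces:
            vec = np.zeros(5)
            vec[INFARCT] = a_lv * f_inf
            vec[NON_INFARCTED_AAR] = a_lv * f_aarni
            vec[REMOTE] = a_lv * f_rem
            face_area_vecs.append(vec)
        if len(face_area_vecs) == 1:
            face_area_vecs.append(None)
        per_slice.append(
            slice_class_masses(face_area_vecs[0], face_area_vecs[1],
                               mass_g, slice_index=idx)
        )
    return infarct_size(per_slice)


def true_is(gt: GroundTruth, experiment_id: str) -> ISResult:
    """The generator's exact IS/AAR for one experiment (continuous geometry)."""
    try:
        return gt.results[experiment_id]
    except KeyError:
        raise LookupError(f"unknown experiment id: {experiment_id!r}") from None
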