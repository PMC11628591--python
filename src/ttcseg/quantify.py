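"""Mass-normalized infarct-size quantification from per-face tissue areas.

Infarct size (IS) is the study endpoint: the mass of infarcted tissue as a
percentage of the mass of the area at risk (AAR).  Surface areas of the
tissue classes are measured on the apical and basal cut faces of each slice,
averaged per slice, and converted to masses with the weighed slice mass —
the mass normalization counteracts varying slice thicknesses.

For slice ``s`` with weighed mass ``m_s`` and per-class mean face areas
``Ā_c``  (c ∈ {infarct, non-infarcted AAR, remote}):

    Ā_LV   = Ā_inf + Ā_aarNI + Ā_rem
    m_c,s  = m_s · Ā_c / Ā_LV

    IS (% of AAR)  = 100 · Σ_s m_inf,s / Σ_s (m_inf,s + m_aarNI,s)
    AAR (% of LV)  = 100 · Σ_s (m_inf,s + m_aarNI,s) / Σ_s m_LV,s

Background/remaining and right-ventricular pixels carry no left-ventricular
mass.  The identical code path serves human annotations and model
predictions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .annotations import ExperimentRecord, areas_from_mask
from .scheme import INFARCT, NON_INFARCTED_AAR, REMOTE

__all__ = [
    "ISResult",
    "SliceMasses",
    "slice_class_masses",
    "infarct_size",
    "quantify_from_masks",
    "DegenerateSliceError",
    "UndefinedISError",
]


class DegenerateSliceError(ValueError):
    """A slice has no left-ventricular area on any available face."""


class UndefinedISError(ValueError):
    """Total AAR mass is zero: IS is undefined without an area at risk."""


@dataclasses.dataclass
class SliceMasses:
    """Left-ventricular tissue masses of one slice, in grams."""

    slice_index: int
    infarct_g: float
    non_infarcted_aar_g: float
    remote_g: float

    @property
    def lv_g(self) -> float:
        return self.infarct_g + self.non_infarcted_aar_g + self.remote_g


@dataclasses.dataclass
class ISResult:
    """Experiment-level infarct size with its per-slice mass breakdown."""

    is_pct_aar: float
    aar_pct_lv: float
    slice_masses: list[SliceMasses]

    @property
    def total_infarct_g(self) -> float:
        return sum(s.infarct_g for s in self.slice_masses)

    @property
    def total_aar_g(self) -> float:
        return sum(s.infarct_g + s.non_infarcted_aar_g for s in self.slice_masses)

    @property
    def total_lv_g(self) -> float:
        return sum(s.lv_g for s in self.slice_masses)


def slice_class_masses(
    areas_apical: np.ndarray | None,
    areas_basal: np.ndarray | None,
    mass_g: float,
    slice_index: int = 0,
) -> SliceMasses:
    """Average the available faces' areas and normalize to the slice mass.

    Parameters
    ----------
    areas_apical, areas_basal
        Per-class areas (length-5 vectors, any consistent unit) of the two
        cut faces; pass ``None`` for an absent (outermost) face, in which
        case the average reduces to the single available face.
    mass_g
        Weighed mass of the whole slice, grams.
    """
    if mass_g <= 0:
        raise ValueError(f"slice mass must be positive, got {mass_g}")
    faces = [np.asarray(a, dtype=float) for a in (areas_apical, areas_basal)
             if a is not None]
    if not faces:
        raise ValueError("both faces missing: cannot quantify slice")
    mean_areas = np.mean(faces, axis=0)
    a_inf = mean_areas[INFARCT]
    a_aarni = mean_areas[NON_INFARCTED_AAR]
    a_rem = mean_areas[REMOTE]
    a_lv = a_inf + a_aarni + a_rem
    if a_lv <= 0:
        raise DegenerateSliceError(
            f"slice {slice_index}: no left-ventricular area on any face"
        )
    scale = mass_g / a_lv
    return SliceMasses(
        slice_index=slice_index,
        infarct_g=a_inf * scale,
        non_infarcted_aar_g=a_aarni * scale,
        remote_g=a_rem * scale,
    )


def infarct_size(slice_masses: list[SliceMasses]) -> ISResult:
    """Sum per-slice LV masses and form the experiment-level ratios."""
    if not slice_masses:
        raise ValueError("need at least one quantified slice")
    total_inf = sum(s.infarct_g for s in slice_masses)
    total_aar = sum(s.infarct_g + s.non_infarcted_aar_g for s in slice_masses)
    total_lv = sum(s.lv_g for s in slice_masses)
    if total_aar <= 0:
        raise UndefinedISError(
            "total AAR mass is zero: infarct size undefined without an AAR"
        )
    return ISResult(
        is_pct_aar=100.0 * total_inf / total_aar,
        aar_pct_lv=100.0 * total_aar / total_lv,
        slice_masses=list(slice_masses),
    )


def quantify_from_masks(
    experiment: ExperimentRecord,
    masks: dict[tuple[int, str], np.ndarray] | None = None,
) -> ISResult:
    """Quantify IS for one experiment from label masks.

    ``masks`` maps ``(slice_index, face)`` to a predicted mask; when omitted
    the annotation masks stored on the record are used.  Predictions and
    annotations run through the identical area → mass → ratio path.
    """
    per_slice = []
    for s in experiment.slices:
        face_areas: dict[str, np.ndarray | None] = {"apical": None, "basal": None}
        for face, _img, ann_mask in s.faces():
            mask = ann_mask if masks is None else masks.get((s.slice_index, face))
            if mask is not None:
                face_areas[face] = areas_from_mask(mask)
        per_slice.append(
            slice_class_masses(
                face_areas["apical"], face_areas["basal"], s.mass_g,
                slice_index=s.slice_index,
            )
        )
    return infarct_size(per_slice)
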