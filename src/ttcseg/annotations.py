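"""Label-mask I/O, pixel-area extraction and experiment-level data splitting.

Masks are stored as indexed (palettized) PNGs whose palette is the class
display palette, so they round-trip bit-exactly and render as a sensible
overlay in any image viewer.  Splitting is always by *experiment* (heart),
never by image: the two faces of a slice, and all slices of a heart, stay on
the same side of every train/validation/test boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.model_selection import KFold

from .scheme import DISPLAY_PALETTE, N_CLASSES

__all__ = [
    "SliceRecord",
    "ExperimentRecord",
    "FoldSplit",
    "write_mask",
    "read_mask",
    "areas_from_mask",
    "area_table",
    "split_experiments",
    "make_folds",
    "write_metadata",
    "read_metadata",
]


class MaskFormatError(ValueError):
    """A mask file contains indices outside the five-class scheme."""


@dataclasses.dataclass
class SliceRecord:
    """One transverse heart slice: mass plus up to two imaged cut faces."""

    slice_index: int            # 1-based from the apex
    mass_g: float
    apical_image: np.ndarray | None = None   # HxWx3 uint8
    apical_mask: np.ndarray | None = None    # HxW uint8 class indices
    basal_image: np.ndarray | None = None
    basal_mask: np.ndarray | None = None

    def faces(self):
        """Yield ``(face_name, image, mask)`` for every present face."""
        if self.apical_image is not None:
            yield "apical", self.apical_image, self.apical_mask
        if self.basal_image is not None:
            yield "basal", self.basal_image, self.basal_mask


@dataclasses.dataclass
class ExperimentRecord:
    """One heart: an ordered stack of weighed slices, apex to base."""

    experiment_id: str
    group: str                  # "IR" or "IR_protected"
    slices: list[SliceRecord]

    def __post_init__(self):
        if not self.slices:
            raise ValueError(f"experiment {self.experiment_id} has no slices")
        for s in self.slices:
            if s.mass_g <= 0:
                raise ValueError(
                    f"experiment {self.experiment_id} slice {s.slice_index}: "
                    f"mass must be positive, got {s.mass_g}"
                )


@dataclasses.dataclass
class FoldSplit:
    """Experiment-level test/cross-validation split plus k CV folds."""

    test_ids: list[str]
    cv_ids: list[str]
    folds: list[tuple[list[str], list[str]]]  # (train_ids, val_ids) per fold


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a class-index mask as an indexed PNG (lossless)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.min() < 0 or mask.max() >= N_CLASSES:
        raise MaskFormatError(
            f"mask contains class indices outside 0..{N_CLASSES - 1}"
        )
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = [c for rgb in DISPLAY_PALETTE for c in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(Path(path), format="PNG")


def read_mask(path: str | Path) -> np.ndarray:
    """Read an indexed-PNG mask; reject indices outside the scheme."""
    with Image.open(Path(path)) as img:
        arr = np.asarray(img)
    if arr.ndim != 2:
        raise MaskFormatError(f"{path}: not an indexed single-channel PNG")
    if arr.max() >= N_CLASSES:
        raise MaskFormatError(
            f"{path}: class index {int(arr.max())} outside the 5-class scheme"
        )
    return arr.astype(np.uint8)


def areas_from_mask(mask: np.ndarray) -> np.ndarray:
    """Per-class pixel areas; five non-negative ints summing to H*W."""
    mask = np.asarray(mask)
    return np.bincount(mask.ravel(), minlength=N_CLASSES)[:N_CLASSES]


def area_table(experiments: Sequence[ExperimentRecord]) -> pd.DataFrame:
    """Tabulate per-face per-class pixel areas for a cohort.

    One row per (experiment, slice, face, class); the mask is the annotation
    stored on the record.
    """
    rows = []
    for exp in experiments:
        for s in exp.slices:
            for face, _img, mask in s.faces():
                if mask is None:
                    continue
                areas = areas_from_mask(mask)
                for c, a in enumerate(areas):
                    rows.append(
                        (exp.experiment_id, s.slice_index, face, c, int(a))
                    )
    return pd.DataFrame(
        rows,
        columns=["experiment_id", "slice_index", "face", "class", "pixel_area"],
    )


def split_experiments(
    ids: Sequence[str], n_test: int, seed: int
) -> tuple[list[str], list[str]]:
    """Split experiment ids into (cv_ids, test_ids), seed-reproducible.

    The split is by experiment, never by image, so no heart contributes
    images to both sides.
    """
    ids = list(ids)
    if n_test >= len(ids):
        raise ValueError(
            f"n_test={n_test} must be smaller than the number of ids ({len(ids)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    test_ids = sorted(ids[i] for i in order[:n_test])
    cv_ids = sorted(ids[i] for i in order[n_test:])
    return cv_ids, test_ids


def make_folds(
    cv_ids: Sequence[str], k: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """k-fold partition of experiment ids into (train_ids, val_ids) pairs.

    Validation sets partition ``cv_ids``; with k folds each fold trains on a
    (k-1)/k share of the ids (fivefold: 80% training, 20% validation).
    """
    cv_ids = list(cv_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(cv_ids):
        raise ValueError(f"k={k} exceeds the number of cv ids ({len(cv_ids)})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, val_idx in kf.split(cv_ids):
        folds.append(
            (sorted(cv_ids[i] for i in train_idx),
             sorted(cv_ids[i] for i in val_idx))
        )
    return folds


def full_split(ids: Sequence[str], n_test: int, k: int, seed: int) -> FoldSplit:
    """Convenience: test/cv split followed by k-fold partition of the cv ids."""
    cv_ids, test_ids = split_experiments(ids, n_test, seed)
    return FoldSplit(test_ids=test_ids, cv_ids=cv_ids,
                     folds=make_folds(cv_ids, k, seed))


# -- slice metadata CSV: one row per slice, hand-editable ---------------------

_META_COLUMNS = [
    "experiment_id", "group", "slice_index", "mass_g",
    "apical_image", "basal_image", "apical_mask", "basal_mask",
]


def write_metadata(experiments: Sequence[ExperimentRecord],
                   paths: dict, csv_path: str | Path) -> None:
    """Write the cohort metadata CSV.

    ``paths`` maps ``(experiment_id, slice_index, face, kind)`` with kind in
    {"image", "mask"} to a file path string; missing entries become empty
    cells (absent face).
    """
    rows = []
    for exp in experiments:
        for s in exp.slices:
            key = (exp.experiment_id, s.slice_index)
            rows.append({
                "experiment_id": exp.experiment_id,
                "group": exp.group,
                "slice_index": s.slice_index,
                "mass_g": s.mass_g,
                "apical_image": paths.get(key + ("apical", "image"), ""),
                "basal_image": paths.get(key + ("basal", "image"), ""),
                "apical_mask": paths.get(key + ("apical", "mask"), ""),
                "basal_mask": paths.get(key + ("basal", "mask"), ""),
            })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(csv_path, index=False)


def read_metadata(csv_path: str | Path) -> pd.DataFrame:
    """Read the cohort metadata CSV back as a DataFrame."""
    df = pd.read_csv(csv_path, dtype={"experiment_id": str}, keep_default_na=False)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def save_cohort(experiments: Sequence[ExperimentRecord], root: str | Path) -> Path:
    """Write a cohort to disk: RGB PNG images, indexed-PNG masks, and the
    slice metadata CSV.  Returns the metadata path."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    for exp in experiments:
        for s in exp.slices:
            for face, img, mask in s.faces():
                stem = f"{exp.experiment_id}_s{s.slice_index:02d}_{face}"
                img_rel = f"images/{stem}.png"
                Image.fromarray(img).save(root / img_rel)
                paths[(exp.experiment_id, s.slice_index, face, "image")] = img_rel
                if mask is not None:
                    mask_rel = f"masks/{stem}.png"
                    write_mask(mask, root / mask_rel)
                    paths[(exp.experiment_id, s.slice_index, face, "mask")] = mask_rel
    csv_path = root / "metadata.csv"
    write_metadata(experiments, paths, csv_path)
    return csv_path


def load_cohort(csv_path: str | Path) -> list[ExperimentRecord]:
    """Rebuild a cohort from its metadata CSV (paths relative to the CSV)."""
    csv_path = Path(csv_path)
    root = csv_path.parent
    df = read_metadata(csv_path)
    experiments: list[ExperimentRecord] = []
    for exp_id, sub in df.groupby("experiment_id", sort=True):
        slices = []
        for _, row in sub.sort_values("slice_index").iterrows():
            rec = SliceRecord(slice_index=int(row["slice_index"]),
                              mass_g=float(row["mass_g"]))
            for face in ("apical", "basal"):
                img_rel = row[f"{face}_image"]
                if img_rel:
                    with Image.open(root / img_rel) as im:
                        setattr(rec, f"{face}_image",
                                np.asarray(im.convert("RGB")))
                mask_rel = row[f"{face}_mask"]
                if mask_rel:
                    setattr(rec, f"{face}_mask", read_mask(root / mask_rel))
            slices.append(rec)
        experiments.append(ExperimentRecord(
            experiment_id=str(exp_id), group=str(sub["group"].iloc[0]),
            slices=slices))
    return experiments
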