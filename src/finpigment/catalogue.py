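"""Photo-catalogue I/O and photographic-quality grading.

A catalogue pairs raster images of segmented dorsal fins with binary fin
masks and per-photo metadata (individual identity, encounter date, session,
photographic-quality category grades).  Images and masks live on disk as
PNG/TIFF; metadata is a UTF-8 CSV with one row per photo.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "FinPhoto",
    "PQGrade",
    "Catalogue",
    "CatalogueError",
    "read_catalogue",
    "write_catalogue",
    "pq_score",
    "filter_by_grade",
    "GradeThresholds",
    "CLARITY_SCORES",
    "CONTRAST_SCORES",
    "ANGLE_SCORES",
    "EDGE_SCORES",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = (
    "image_id",
    "individual_id",
    "date",
    "session_id",
    "image_file",
    "mask_file",
    "clarity",
    "contrast",
    "angle",
    "edge",
)

#: Category score maps for photographic-quality grading.
CLARITY_SCORES: Mapping[str, int] = {"poor": 1, "reasonable": 4, "excellent": 9}
CONTRAST_SCORES: Mapping[str, int] = {"poor": 1, "reasonable": 3, "excellent": 9}
ANGLE_SCORES: Mapping[str, int] = {"poor": 1, "reasonable": 2, "excellent": 9}
EDGE_SCORES: Mapping[str, int] = {"poor_reasonable": 1, "excellent": 8}


class CatalogueError(ValueError):
    """Raised for malformed catalogue inputs."""


@dataclass(frozen=True)
class GradeThresholds:
    """Total-score cut-offs mapping a quality score to a grade label.

    Any category at its minimum score forces the grade "poor" regardless of
    the total; otherwise the total is compared against the cut-offs.
    """

    good: int = 20
    excellent: int = 30


@dataclass(frozen=True)
class PQGrade:
    """Photographic-quality grade: four category scores plus the summed total."""

    clarity_focus: int
    contrast: int
    orientation_angle: int
    edge_visibility: int
    total: int
    grade_label: str

    def __post_init__(self) -> None:
        if self.total != self.clarity_focus + self.contrast + self.orientation_angle + self.edge_visibility:
            raise CatalogueError("PQGrade total must equal the sum of category scores")
        if not (4 <= self.total <= 35):
            raise CatalogueError(f"PQGrade total {self.total} outside [4, 35]")


@dataclass
class FinPhoto:
    """One catalogue record: grey/RGB pixels, binary fin mask, metadata."""

    image_id: str
    individual_id: str  # "" for unidentified query photos
    date: _dt.date
    session_id: str
    pixels: np.ndarray
    mask: np.ndarray
    grade: PQGrade | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape[:2]:
            raise CatalogueError(
                f"{self.image_id}: mask shape {self.mask.shape} does not match "
                f"image shape {self.pixels.shape[:2]}"
            )
        validate_mask(self.mask, image_id=self.image_id)

    def sort_key(self) -> tuple:
        # deterministic ordering: date, then session, then image id
        return (self.date, self.session_id, self.image_id)


def validate_mask(mask: np.ndarray, *, image_id: str = "?", allow_multi: bool = False) -> np.ndarray:
    """Check the fin-mask invariants: non-empty, single 4-connected component.

    With ``allow_multi`` the largest component is kept instead of raising.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise CatalogueError(f"{image_id}: empty mask")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    if n > 1:
        if not allow_multi:
            raise CatalogueError(
                f"{image_id}: mask has {n} connected components (expected 1); "
                "pass keep_largest_component to take the largest"
            )
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        return labels == keep
    return mask


@dataclass
class Catalogue:
    """An ordered collection of :class:`FinPhoto` records."""

    photos: list[FinPhoto] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.image_id for p in self.photos]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogueError(f"duplicate image_id values: {dupes}")

    @property
    def individuals(self) -> set[str]:
        return {p.individual_id for p in self.photos if p.individual_id}

    def __len__(self) -> int:
        return len(self.photos)

    def __iter__(self):
        return iter(self.photos)

    def __getitem__(self, image_id: str) -> FinPhoto:
        for p in self.photos:
            if p.image_id == image_id:
                return p
        raise KeyError(image_id)

    def sorted_by_date(self) -> "Catalogue":
        return Catalogue(sorted(self.photos, key=FinPhoto.sort_key))


def _read_raster(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im)
    return arr


def read_catalogue(
    metadata_path: str | Path,
    image_root: str | Path | None = None,
    *,
    keep_largest_component: bool = False,
) -> Catalogue:
    """Read a catalogue from a metadata CSV plus image/mask files.

    Parameters
    ----------
    metadata_path
        CSV with columns ``image_id, individual_id, date, session_id,
        image_file, mask_file`` and optionally the four PQ category columns.
    image_root
        Directory that image/mask paths are relative to; defaults to the
        CSV's directory.
    keep_largest_component
        Permissively keep the largest 4-connected mask component instead of
        rejecting multi-component masks.
    """
    metadata_path = Path(metadata_path)
    root = Path(image_root) if image_root is not None else metadata_path.parent
    df = pd.read_csv(metadata_path, dtype=str, keep_default_na=False)
    required = {"image_id", "individual_id", "date", "session_id", "image_file", "mask_file"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogueError(f"metadata CSV missing columns: {sorted(missing)}")

    photos: list[FinPhoto] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        image_path = root / row.image_file
        mask_path = root / row.mask_file
        for p in (image_path, mask_path):
            if not p.exists():
                raise CatalogueError(f"row {row_no} ({row.image_id}): file not found: {p}")
        pixels = _read_raster(image_path)
        mask = _read_raster(mask_path)
        if mask.ndim != 2:
            raise CatalogueError(f"row {row_no} ({row.image_id}): mask must be single-channel")
        mask_bool = validate_mask(mask != 0, image_id=row.image_id, allow_multi=keep_largest_component)
        try:
            date = _dt.date.fromisoformat(row.date)
        except ValueError as exc:
            raise CatalogueError(f"row {row_no} ({row.image_id}): bad date {row.date!r}") from exc
        grade = None
        if all(hasattr(row, c) and getattr(row, c) for c in ("clarity", "contrast", "angle", "edge")):
            grade = pq_score(row.clarity, row.contrast, row.angle, row.edge)
        photos.append(
            FinPhoto(
                image_id=row.image_id,
                individual_id=row.individual_id,
                date=date,
                session_id=row.session_id,
                pixels=pixels,
                mask=mask_bool,
                grade=grade,
            )
        )
    return Catalogue(photos)


def write_catalogue(
    catalogue: Catalogue,
    out_dir: str | Path,
    *,
    category_labels: Mapping[str, tuple[str, str, str, str]] | None = None,
) -> Path:
    """Write images, masks and ``metadata.csv`` under ``out_dir``.

    Masks are stored as 8-bit single-channel PNG with 0 = background and
    255 = fin.  Returns the metadata CSV path.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for photo in catalogue:
        image_file = f"images/{photo.image_id}.png"
        mask_file = f"masks/{photo.image_id}.png"
        pixels = photo.pixels
        if pixels.dtype != np.uint8:
            pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
        Image.fromarray(pixels).save(out_dir / image_file)
        Image.fromarray(photo.mask.astype(np.uint8) * 255).save(out_dir / mask_file)
        labels = ("", "", "", "")
        if category_labels and photo.image_id in category_labels:
            labels = category_labels[photo.image_id]
        rows.append(
            {
                "image_id": photo.image_id,
                "individual_id": photo.individual_id,
                "date": photo.date.isoformat(),
                "session_id": photo.session_id,
                "image_file": image_file,
                "mask_file": mask_file,
                "clarity": labels[0],
                "contrast": labels[1],
                "angle": labels[2],
                "edge": labels[3],
            }
        )
    csv_path = out_dir / "metadata.csv"
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(csv_path, index=False)
    return csv_path


def pq_score(
    clarity: str,
    contrast: str,
    angle: str,
    edge: str,
    thresholds: GradeThresholds = GradeThresholds(),
) -> PQGrade:
    """Score the four photographic-quality categories and assign a grade.

    Category labels map to fixed integer scores (clarity poor/reasonable/
    excellent -> 1/4/9; contrast -> 1/3/9; angle -> 1/2/9; edge
    poor_reasonable/excellent -> 1/8).  The scores are weighted so that any
    single category at its minimum forces the overall grade "poor"; otherwise
    the summed total is compared with the configurable cut-offs.
    """
    scores = []
    for label, table, name in (
        (clarity, CLARITY_SCORES, "clarity"),
        (contrast, CONTRAST_SCORES, "contrast"),
        (angle, ANGLE_SCORES, "angle"),
        (edge, EDGE_SCORES, "edge"),
    ):
        key = str(label).strip().lower()
        if key not in table:
            raise CatalogueError(f"unknown {name} label {label!r}; expected one of {sorted(table)}")
        scores.append(table[key])
    total = sum(scores)
    minima = (
        min(CLARITY_SCORES.values()),
        min(CONTRAST_SCORES.values()),
        min(ANGLE_SCORES.values()),
        min(EDGE_SCORES.values()),
    )
    if any(s == m for s, m in zip(scores, minima)):
        label = "poor"
    elif total >= thresholds.excellent:
        label = "excellent"
    elif total >= thresholds.good:
        label = "good"
    else:
        label = "poor"
    return PQGrade(
        clarity_focus=scores[0],
        contrast=scores[1],
        orientation_angle=scores[2],
        edge_visibility=scores[3],
        total=total,
        grade_label=label,
    )


def filter_by_grade(catalogue: Catalogue, grades: Iterable[str]) -> Catalogue:
    """Keep only photos whose grade label is in ``grades``, preserving order."""
    keep = set(grades)
    retained = []
    for photo in catalogue:
        if photo.grade is None:
            raise CatalogueError(f"{photo.image_id}: no photographic-quality grade assigned")
        if photo.grade.grade_label in keep:
            retained.append(photo)
    if not retained:
        warnings.warn("filter_by_grade retained no photos", stacklevel=2)
    return Catalogue(retained)
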