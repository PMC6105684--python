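"""End-to-end feature extraction over a catalogue.

For each photo: grey conversion, within-mask normalisation, optional ICP
pose registration into a reference frame, base estimation, the two patch
subdivisions, and the 142-feature descriptor.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from finpigment.catalogue import Catalogue, FinPhoto
from finpigment.features import FEATURE_NAMES, extract_feature_vector
from finpigment.preprocess import normalise, to_grey
from finpigment.registration import FinContour, ICPConfig, extract_contour, icp_register, warp_fin
from finpigment.subdivision import contour_subdivide, estimate_base, grid_subdivide

__all__ = ["extract_catalogue_features", "choose_reference", "extract_photo_features"]

log = logging.getLogger(__name__)


def extract_photo_features(
    photo: FinPhoto,
    *,
    register_to: FinContour | None = None,
    reference_shape: tuple[int, int] | None = None,
    icp_config: ICPConfig = ICPConfig(),
) -> np.ndarray:
    """Feature vector for one photo, optionally pose-registered first."""
    fin = normalise(to_grey(photo.pixels), photo.mask)
    if register_to is not None:
        contour = extract_contour(photo.mask)
        tf = icp_register(contour, register_to, icp_config)
        fin = warp_fin(fin, tf, reference_shape or photo.mask.shape)
    contour = extract_contour(fin.mask)
    base = estimate_base(contour)
    grid = grid_subdivide(fin.mask, base)
    cont = contour_subdivide(fin.mask, contour, base)
    return extract_feature_vector(fin, grid, cont).values


def choose_reference(catalogue: Catalogue, *, per_individual: bool = False):
    """Pick registration reference contour(s): the photo with the highest
    photographic-quality total (ties by image_id), globally or per
    individual.  Photos without a grade count as total 0."""

    def total(p: FinPhoto) -> int:
        return p.grade.total if p.grade is not None else 0

    if not per_individual:
        best = max(catalogue, key=lambda p: (total(p), p.image_id))
        return extract_contour(best.mask), best.mask.shape
    refs = {}
    for p in catalogue:
        key = p.individual_id or p.image_id
        if key not in refs or (total(p), p.image_id) > refs[key][0]:
            refs[key] = ((total(p), p.image_id), p)
    return {k: (extract_contour(p.mask), p.mask.shape) for k, ((_, _), p) in refs.items()}


def extract_catalogue_features(
    catalogue: Catalogue,
    *,
    register: bool = False,
    per_individual_reference: bool = False,
    strict: bool = False,
    icp_config: ICPConfig = ICPConfig(),
) -> pd.DataFrame:
    """Feature matrix for a catalogue: image_id, individual_id, date plus
    the 142 named feature columns.

    Unusable photos are skipped with a logged reason (or re-raised in
    ``strict`` mode).
    """
    if register:
        refs = choose_reference(catalogue, per_individual=per_individual_reference)
    rows = []
    n_failed = 0
    for photo in catalogue:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if register:
                    if per_individual_reference:
                        ref_contour, ref_shape = refs[photo.individual_id or photo.image_id]
                    else:
                        ref_contour, ref_shape = refs
                    values = extract_photo_features(
                        photo, register_to=ref_contour, reference_shape=ref_shape, icp_config=icp_config
                    )
                else:
                    values = extract_photo_features(photo)
        except Exception as exc:  # noqa: BLE001 - per-photo isolation
            if strict:
                raise
            n_failed += 1
            log.warning("skipping %s: %s", photo.image_id, exc)
            continue
        rows.append(
            {"image_id": photo.image_id, "individual_id": photo.individual_id, "date": photo.date.isoformat()}
            | dict(zip(FEATURE_NAMES, values))
        )
    log.info("extracted features for %d/%d photos (%d skipped)", len(rows), len(catalogue), n_failed)
    return pd.DataFrame(rows, columns=["image_id", "individual_id", "date", *FEATURE_NAMES])
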