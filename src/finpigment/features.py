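"""The 142-dimensional pigmentation feature vector.

126 per-patch statistics (mean, median, IQR over the normalised intensities
of each of the 33 grid and 9 contour patches) plus 16 inter-patch features
(spreads and central tendencies of the per-patch statistic distributions).
Quantiles interpolate linearly between order statistics at rank (n-1)p;
standard deviations use the population convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from finpigment.preprocess import NormalisedFin
from finpigment.subdivision import CONTOUR_PATCH_COUNT, GRID_PATCH_COUNT, ContourPartition, GridPartition

__all__ = [
    "FeatureVector",
    "FeatureError",
    "patch_stats",
    "interpatch_features",
    "extract_feature_vector",
    "FEATURE_NAMES",
    "N_FEATURES",
    "INTERPATCH_NAMES",
]

_STAT_NAMES = ("mean", "median", "iqr")

INTERPATCH_NAMES = (
    "std_grid_means",
    "std_grid_medians",
    "std_grid_iqrs",
    "iqr_grid_means",
    "iqr_grid_medians",
    "iqr_grid_iqrs",
    "mean_grid_iqrs",
    "median_grid_iqrs",
    "std_cont_means",
    "std_cont_medians",
    "std_cont_iqrs",
    "iqr_cont_means",
    "iqr_cont_medians",
    "iqr_cont_iqrs",
    "mean_cont_iqrs",
    "median_cont_iqrs",
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"grid{p:02d}_{s}" for p in range(1, GRID_PATCH_COUNT + 1) for s in _STAT_NAMES]
    + [f"cont{p}_{s}" for p in range(1, CONTOUR_PATCH_COUNT + 1) for s in _STAT_NAMES]
    + list(INTERPATCH_NAMES)
)
N_FEATURES = len(FEATURE_NAMES)  # 142


class FeatureError(ValueError):
    pass


@dataclass
class FeatureVector:
    """Ordered 142-feature pigmentation descriptor with missingness flags."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise FeatureError(f"expected {len(self.names)} features, got {self.values.shape}")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def __len__(self) -> int:
        return len(self.values)


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation at rank (n-1)p
    return float(q3 - q1)


def patch_stats(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, median, IQR) of a patch's intensities; NaNs for an empty patch."""
    values = np.asarray(values, dtype=np.float64)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return (float("nan"),) * 3
    return float(values.mean()), float(np.median(values)), _iqr(values)


def _spread_block(table: np.ndarray) -> list[float]:
    """[std(means), std(medians), std(iqrs), IQR(means), IQR(medians),
    IQR(iqrs), mean(iqrs), median(iqrs)] for one patch-statistic table."""
    out: list[float] = []
    cols = [table[:, 0], table[:, 1], table[:, 2]]
    for col in cols:
        avail = col[~np.isnan(col)]
        out.append(float(avail.std()) if avail.size >= 2 else float("nan"))
    for col in cols:
        avail = col[~np.isnan(col)]
        out.append(_iqr(avail) if avail.size >= 2 else float("nan"))
    iqrs = cols[2][~np.isnan(cols[2])]
    out.append(float(iqrs.mean()) if iqrs.size else float("nan"))
    out.append(float(np.median(iqrs)) if iqrs.size else float("nan"))
    return out


def interpatch_features(grid_stats: np.ndarray, contour_stats: np.ndarray) -> np.ndarray:
    """The 16 inter-patch features, grid block first then contour block.

    Each input is an (n_patches, 3) table of (mean, median, IQR) rows;
    missing rows (NaN) are excluded per statistic.
    """
    grid_stats = np.asarray(grid_stats, dtype=np.float64)
    contour_stats = np.asarray(contour_stats, dtype=np.float64)
    if grid_stats.shape != (GRID_PATCH_COUNT, 3) or contour_stats.shape != (CONTOUR_PATCH_COUNT, 3):
        raise FeatureError(
            f"expected stat tables of shape ({GRID_PATCH_COUNT}, 3) and "
            f"({CONTOUR_PATCH_COUNT}, 3), got {grid_stats.shape} and {contour_stats.shape}"
        )
    return np.array(_spread_block(grid_stats) + _spread_block(contour_stats))


def extract_feature_vector(
    fin: NormalisedFin,
    grid: GridPartition,
    contour: ContourPartition,
    *,
    max_missing_fraction: float = 0.25,
) -> FeatureVector:
    """Compute the full 142-feature descriptor for one normalised fin."""
    if fin.values.shape != grid.labels.shape or fin.values.shape != contour.labels.shape:
        raise FeatureError("fin and partitions must share raster dimensions")

    grid_tab = np.array(
        [patch_stats(fin.values[grid.labels == p]) for p in range(1, GRID_PATCH_COUNT + 1)]
    )
    cont_tab = np.array(
        [patch_stats(fin.values[contour.labels == p]) for p in range(1, CONTOUR_PATCH_COUNT + 1)]
    )
    inter = interpatch_features(grid_tab, cont_tab)
    values = np.concatenate([grid_tab.ravel(), cont_tab.ravel(), inter])
    missing_frac = np.isnan(values).mean()
    if missing_frac > max_missing_fraction:
        raise FeatureError(
            f"unusable image: {missing_frac:.0%} of features missing "
            f"(threshold {max_missing_fraction:.0%})"
        )
    return FeatureVector(values=values)
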