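"""Temporal stability of pigmentation: permutation seriation tests with
Šidák family-wise error control, and discriminant-space trajectories.

The seriation test is Mantel-type: the observed statistic is the Spearman
rank correlation between the pairwise feature-space Euclidean distances of
one individual's photos and their pairwise encounter-order distances.  Under
the null the photographic order is arbitrary, so the null distribution is
obtained by permuting the time order; the alternative is one-sided (a
directional drift makes photos taken further apart in time sit further
apart in feature space).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from finpigment import classify

__all__ = [
    "SeriationResult",
    "TemporalError",
    "sidak_alpha",
    "seriation_test",
    "stability_screen",
    "lda_trajectory",
]


class TemporalError(ValueError):
    pass


@dataclass
class SeriationResult:
    individual_id: str
    n_images: int
    statistic: float
    p_value: float
    alpha_sidak: float
    reject: bool
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise TemporalError(f"p-value {self.p_value} outside (0, 1]")
        if self.reject != (self.p_value < self.alpha_sidak):
            raise TemporalError("reject flag inconsistent with p-value and alpha")


def sidak_alpha(m: int, fwer: float = 0.05) -> float:
    """Per-test level alpha = 1 - (1 - fwer)^(1/m) controlling the
    family-wise error rate over m independent tests."""
    if m < 1:
        raise TemporalError(f"number of tests must be >= 1, got {m}")
    if not (0.0 < fwer < 1.0):
        raise TemporalError(f"family-wise rate must be in (0, 1), got {fwer}")
    return 1.0 - (1.0 - fwer) ** (1.0 / m)


def _spearman_against(fixed_ranks: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of ``rows`` with a fixed rank vector."""
    row_ranks = rankdata(rows, axis=-1)
    fr = fixed_ranks - fixed_ranks.mean()
    rr = row_ranks - row_ranks.mean(axis=-1, keepdims=True)
    denom = np.sqrt((fr**2).sum() * (rr**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (rr @ fr) / denom
    return np.where(denom > 0, out, 0.0)


def seriation_test(
    vectors: np.ndarray,
    time_order: np.ndarray | None = None,
    *,
    n_permutations: int = 9999,
    seed: int = 0,
    individual_id: str = "?",
    alpha: float = 0.05,
    use_calendar_gaps: bool = False,
    times: np.ndarray | None = None,
) -> SeriationResult:
    """Mantel-type permutation test for temporal drift of one individual.

    ``vectors`` are the individual's feature vectors in encounter order
    (rows); ``time_order`` optionally gives their time ranks (default
    0..n-1).  With ``use_calendar_gaps`` the pairwise time distances use
    ``times`` (e.g. days since first encounter) instead of ranks.
    The p-value uses the add-one estimator (1 + #{null >= observed}) /
    (1 + n_permutations) and is one-sided.
    """
    X = np.asarray(vectors, dtype=np.float64)
    n = len(X)
    if n < 3:
        raise TemporalError(f"seriation test needs >= 3 images, got {n}")
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    X = np.where(np.isnan(X), 0.0, X)

    d_feat = pdist(X)
    if use_calendar_gaps:
        if times is None:
            raise TemporalError("use_calendar_gaps requires times")
        t = np.asarray(times, dtype=np.float64)
    elif time_order is not None:
        t = np.asarray(time_order, dtype=np.float64)
    else:
        t = np.arange(n, dtype=np.float64)

    d_time_full = np.abs(t[:, None] - t[None, :])
    d_time = squareform(d_time_full, checks=False)

    if np.allclose(d_feat, 0.0):
        warnings.warn(f"{individual_id}: all feature vectors identical; p = 1", stacklevel=2)
        return SeriationResult(
            individual_id=individual_id, n_images=n, statistic=0.0, p_value=1.0,
            alpha_sidak=alpha, reject=False, n_permutations=n_permutations, seed=seed,
        )

    feat_ranks = rankdata(d_feat)
    observed = float(_spearman_against(feat_ranks, d_time[None, :])[0])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    iu = np.triu_indices(n, k=1)
    null_rows = d_time_full[perms[:, iu[0]], perms[:, iu[1]]]
    null_stats = _spearman_against(feat_ranks, null_rows)
    p = (1.0 + float((null_stats >= observed - 1e-12).sum())) / (1.0 + n_permutations)
    return SeriationResult(
        individual_id=individual_id,
        n_images=n,
        statistic=observed,
        p_value=p,
        alpha_sidak=alpha,
        reject=p < alpha,
        n_permutations=n_permutations,
        seed=seed,
    )


def _select_individuals(frame: pd.DataFrame, top_n: int) -> list[str]:
    """Rank individuals by (time span of images, then image count), keeping
    only those with >= 3 dated images."""
    stats = []
    for ind, grp in frame.groupby("individual_id"):
        if len(grp) < 3 or not ind:
            continue
        dates = pd.to_datetime(grp["date"])
        stats.append((ind, (dates.max() - dates.min()).days, len(grp)))
    stats.sort(key=lambda s: (-s[1], -s[2], s[0]))
    return [s[0] for s in stats[:top_n]]


def stability_screen(
    features: pd.DataFrame,
    feature_columns: list[str],
    *,
    top_n: int = 15,
    fwer: float = 0.05,
    n_permutations: int = 9999,
    seed: int = 0,
) -> list[SeriationResult]:
    """Seriation-test the ``top_n`` best-sampled individuals at the
    Šidák-corrected per-test level.

    ``features`` needs columns image_id, individual_id, date plus the
    feature columns.  If fewer than ``top_n`` individuals have >= 3 dated
    images, the screen proceeds with what it has and the correction is
    recomputed for the smaller family.
    """
    chosen = _select_individuals(features, top_n)
    if not chosen:
        raise TemporalError("no individual has >= 3 dated images")
    if len(chosen) < top_n:
        warnings.warn(
            f"only {len(chosen)} eligible individuals (requested {top_n}); "
            "recomputing the correction for the smaller family",
            stacklevel=2,
        )
    alpha = sidak_alpha(len(chosen), fwer)
    child_seeds = np.random.SeedSequence(seed).spawn(len(chosen))
    results = []
    for ind, ss in zip(chosen, child_seeds):
        grp = features[features["individual_id"] == ind].copy()
        grp["_date"] = pd.to_datetime(grp["date"])
        grp = grp.sort_values(["_date", "session_id", "image_id"] if "session_id" in grp else ["_date", "image_id"])
        X = grp[feature_columns].to_numpy(dtype=float)
        results.append(
            seriation_test(
                X,
                n_permutations=n_permutations,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                individual_id=str(ind),
                alpha=alpha,
            )
        )
    return results


def lda_trajectory(
    features: pd.DataFrame,
    feature_columns: list[str],
    individuals: list[str] | None = None,
    *,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Project the selected individuals' photos onto the first two
    discriminant axes, ordered by date within individual.

    With two individuals only one axis is informative and axis2 is 0.
    Optionally renders a scatter with date-ordered connecting lines.
    """
    if individuals is None:
        individuals = sorted(features["individual_id"].unique())
    if len(individuals) < 3:
        warnings.warn("fewer than 3 individuals; discriminant axes may be degenerate", stacklevel=2)
    sel = features[features["individual_id"].isin(individuals)].copy()
    if sel["individual_id"].nunique() < 2:
        raise TemporalError("need >= 2 individuals for discriminant axes")
    X = sel[feature_columns].to_numpy(dtype=float)
    y = sel["individual_id"].to_numpy()
    model = classify.fit(X, y)
    axes = classify.discriminant_axes(model, n_axes=2)
    Xi = np.where(np.isnan(X), model.imputation_means, X)
    proj = Xi @ axes
    out = pd.DataFrame(
        {
            "image_id": sel["image_id"].to_numpy(),
            "individual_id": y,
            "date": sel["date"].to_numpy(),
            "axis1": proj[:, 0],
            "axis2": proj[:, 1],
        }
    )
    out = out.sort_values(["individual_id", "date", "image_id"], kind="stable").reset_index(drop=True)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 6))
        for ind, grp in out.groupby("individual_id"):
            ax.plot(grp["axis1"], grp["axis2"], marker="o", ms=4, lw=0.8, label=str(ind))
        ax.set_xlabel("discriminant axis 1")
        ax.set_ylabel("discriminant axis 2")
        ax.set_title("Date-ordered trajectories in discriminant space")
        if len(individuals) <= 15:
            ax.legend(fontsize=7, ncol=2)
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out
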