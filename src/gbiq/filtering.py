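"""Nucleus-grid selection by the Median_IQR filter, and the grid-size advisor.

The filter rests on one observation about dense counterstained material: a
grid lying entirely inside a nucleus has a high median intensity and a small
interquartile range, while a grid straddling a nucleus boundary (nucleus +
cytoplasm or void) has a large IQR. Clustering the (counterstain median,
counterstain IQR) pairs with a BIC-selected Gaussian mixture and keeping the
classes that are simultaneously brighter-than-average and more-uniform-than-
average therefore selects nucleus-pure grids without any segmentation.

Acceptance criteria for a class, relative to all grids of the matrix:

1. class mean of median intensity  >  overall mean of median intensity, and
2. class mean IQR                  <  overall mean IQR.

Every class passing both is selected (their union, when several pass). When
no class passes — the symptom of an over-large grid size — a documented
fallback selects the single class with the highest mean median intensity
among those strictly brighter than the overall mean, and flags itself.

"Overall mean intensity" averages the grid *medians*, not raw pixels: the
filter operates on the grid matrix. Both criteria use strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .gridding import make_gridspec, quantify
from .image_io import MultiChannelImage
from .mixture import COVARIANCE_FAMILIES, Assignment, GaussianMixtureBIC

__all__ = [
    "FilterError",
    "FilterResult",
    "MedianIQRFilter",
    "median_iqr_filter",
    "scan_grid_sizes",
    "recommend_grid_size",
    "RecommendationError",
    "DEFAULT_G_CANDIDATES",
]

#: default grid sizes tried by the scan (the advisor's search range)
DEFAULT_G_CANDIDATES = (8, 10, 12, 16, 20, 24, 30, 40)


class FilterError(RuntimeError):
    """No grid class resembles nuclei (not even the fallback's)."""


class RecommendationError(RuntimeError):
    """Every candidate grid size was excluded; rationale in the message."""


@dataclass(frozen=True)
class FilterResult:
    """Outcome of one Median_IQR filter application.

    Attributes
    ----------
    model : GaussianMixtureBIC
        BIC-selected mixture on the (median, IQR) feature pair.
    assignment : Assignment
        Hard labels + responsibilities for every input grid.
    class_stats : DataFrame
        One row per class: ``n``, ``mean_median``, ``mean_iqr``, and the two
        criterion booleans.
    overall_mean_median, overall_mean_iqr : float
        The criterion reference values over all grids.
    selected_classes : tuple of int
    fallback_used : bool
        True when no class met both criteria and the brightest
        above-average class was taken instead (exactly one class then).
    matrix : DataFrame
        The input matrix with ``filter_class`` and ``filter_selected``
        columns appended.
    selected : DataFrame
        The subset of ``matrix`` in the selected classes.
    """

    model: GaussianMixtureBIC
    assignment: Assignment
    class_stats: pd.DataFrame
    overall_mean_median: float
    overall_mean_iqr: float
    selected_classes: tuple[int, ...]
    fallback_used: bool
    matrix: pd.DataFrame
    selected: pd.DataFrame


class MedianIQRFilter(BaseEstimator):
    """Select nucleus-pure grids from a grid matrix.

    Parameters
    ----------
    counterstain : str
        Channel whose ``_median``/``_iqr`` columns drive the filter
        (the DNA dye: H33342, DAPI, ...).
    k_range : (int, int), default (1, 9)
        Component-count search range of the internal BIC-selected mixture.
    families : tuple of str
        Covariance families scanned (same machinery as the main classifier).
    random_state : int or None

    Attributes (after ``fit``)
    --------------------------
    result_ : FilterResult
    selected_classes_, fallback_used_ : convenience mirrors.
    """

    def __init__(
        self,
        counterstain: str = "H33342",
        k_range: tuple[int, int] = (1, 9),
        families: tuple[str, ...] = COVARIANCE_FAMILIES,
        random_state: int | None = None,
    ):
        self.counterstain = counterstain
        self.k_range = k_range
        self.families = families
        self.random_state = random_state

    def _features(self, matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
        cols = [f"{self.counterstain}_median", f"{self.counterstain}_iqr"]
        missing = [c for c in cols if c not in matrix.columns]
        if missing:
            raise ValueError(
                f"grid matrix lacks counterstain columns {missing}; "
                f"available: {list(matrix.columns)}"
            )
        return cols, matrix[cols].to_numpy(dtype=np.float64)

    def fit(self, X: pd.DataFrame, y=None) -> "MedianIQRFilter":
        cols, feats = self._features(X)
        model = GaussianMixtureBIC(
            k_range=self.k_range, families=self.families,
            random_state=self.random_state,
        ).fit(feats, feature_names=cols)
        resp = model.predict_proba(feats)
        labels = resp.argmax(axis=1)

        med, iqr = feats[:, 0], feats[:, 1]
        overall_med = float(med.mean())
        overall_iqr = float(iqr.mean())
        rows = []
        for j in range(model.k_):
            in_j = labels == j
            mm = float(med[in_j].mean()) if in_j.any() else np.nan
            mi = float(iqr[in_j].mean()) if in_j.any() else np.nan
            rows.append(
                {
                    "class": j,
                    "n": int(in_j.sum()),
                    "mean_median": mm,
                    "mean_iqr": mi,
                    "brighter_than_overall": bool(mm > overall_med),
                    "more_uniform_than_overall": bool(mi < overall_iqr),
                }
            )
        stats = pd.DataFrame(rows)
        passing = stats.loc[
            stats["brighter_than_overall"] & stats["more_uniform_than_overall"],
            "class",
        ].tolist()
        fallback = False
        if passing:
            selected = tuple(int(j) for j in passing)
        else:
            # the documented large-g fallback: brightest class strictly above
            # the overall mean median intensity
            above = stats.loc[stats["brighter_than_overall"]]
            if above.empty:
                raise FilterError(
                    "no nucleus-like class: no class mean median intensity "
                    "exceeds the overall mean"
                )
            selected = (int(above.loc[above["mean_median"].idxmax(), "class"]),)
            fallback = True

        matrix = X.copy()
        matrix["filter_class"] = labels
        matrix["filter_selected"] = np.isin(labels, selected)
        self.result_ = FilterResult(
            model=model,
            assignment=Assignment(labels=labels, responsibilities=resp),
            class_stats=stats,
            overall_mean_median=overall_med,
            overall_mean_iqr=overall_iqr,
            selected_classes=selected,
            fallback_used=fallback,
            matrix=matrix,
            selected=matrix.loc[matrix["filter_selected"]].copy(),
        )
        self.selected_classes_ = selected
        self.fallback_used_ = fallback
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Label grids with the fitted mixture and return the selected subset."""
        _, feats = self._features(X)
        labels = self.result_.model.predict(feats)
        return X.loc[np.isin(labels, self.selected_classes_)].copy()

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).result_.selected


def median_iqr_filter(
    matrix: pd.DataFrame,
    counterstain: str,
    k_range: tuple[int, int] = (1, 9),
    seed: int | None = None,
) -> FilterResult:
    """Apply the Median_IQR filter to a grid matrix; see :class:`MedianIQRFilter`."""
    return MedianIQRFilter(
        counterstain=counterstain, k_range=k_range, random_state=seed
    ).fit(matrix).result_


def scan_grid_sizes(
    image: MultiChannelImage | list[MultiChannelImage],
    counterstain: str,
    g_candidates: tuple[int, ...] = DEFAULT_G_CANDIDATES,
    seed: int | None = None,
    k_range: tuple[int, int] = (1, 9),
) -> pd.DataFrame:
    """Quantify + filter the image at each candidate grid size.

    Returns one row per candidate ``g`` with the grid count, the selected
    class ids, the selected-class grid count and its mean median / mean IQR,
    and the fallback flag. A filter failure at one ``g`` is recorded in that
    row's ``error`` column rather than aborting the scan.
    """
    first = image if isinstance(image, MultiChannelImage) else image[0]
    rows = []
    for g in g_candidates:
        spec = make_gridspec(first.height, first.width, g)
        row: dict[str, object] = {
            "g": g,
            "n_grids": spec.n_grids,
            "selected_classes": "",
            "n_selected": 0,
            "selected_mean_median": np.nan,
            "selected_mean_iqr": np.nan,
            "fallback_used": False,
            "error": "",
        }
        try:
            matrix = quantify(image, g)
            res = median_iqr_filter(matrix, counterstain, k_range=k_range, seed=seed)
            sel = res.selected
            row.update(
                selected_classes="+".join(str(j) for j in res.selected_classes),
                n_selected=len(sel),
                selected_mean_median=float(sel[f"{counterstain}_median"].mean()),
                selected_mean_iqr=float(sel[f"{counterstain}_iqr"].mean()),
                fallback_used=res.fallback_used,
            )
        except (FilterError, ValueError, RuntimeError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def recommend_grid_size(
    report: pd.DataFrame, nucleus_count: int | None = None
) -> tuple[int, str]:
    """Pick a grid size from a scan report, with a human-readable rationale.

    Exclusion rules:

    (i)  with a manual ``nucleus_count``, candidates whose selected-class grid
         count reaches twice that number are rejected — such grids are small
         enough to sample one nucleus several times;
    (ii) candidates where the filter fell back (no class met both criteria)
         are rejected — the over-large-grid symptom;
    plus any candidate whose scan row recorded an error.

    Survivors are ranked by selected-class mean median intensity (brightest
    first), ties broken by selected-class grid count (larger first).
    """
    if len(report) == 0:
        raise ValueError("empty grid-size report")
    notes: list[str] = []
    survivors = []
    for _, row in report.iterrows():
        g = int(row["g"])
        if row.get("error"):
            notes.append(f"g={g}: excluded (filter error: {row['error']})")
            continue
        if nucleus_count is not None and row["n_selected"] >= 2 * nucleus_count:
            notes.append(
                f"g={g}: excluded (selected {int(row['n_selected'])} grids >= "
                f"2 x {nucleus_count} nuclei; grid too small, multiple "
                "sampling per nucleus)"
            )
            continue
        if bool(row["fallback_used"]):
            notes.append(
                f"g={g}: excluded (no class met both filter criteria; "
                "grid too large)"
            )
            continue
        survivors.append(row)
    if not survivors:
        raise RecommendationError(
            "all candidate grid sizes excluded:\n" + "\n".join(notes)
        )
    ranked = sorted(
        survivors,
        key=lambda r: (-float(r["selected_mean_median"]), -int(r["n_selected"])),
    )
    best = ranked[0]
    g_best = int(best["g"])
    notes.append(
        f"g={g_best}: recommended (selected-class mean median intensity "
        f"{float(best['selected_mean_median']):.2f}, "
        f"{int(best['n_selected'])} grids)"
    )
    for r in ranked[1:]:
        notes.append(
            f"g={int(r['g'])}: ranked below g={g_best} "
            f"(mean median {float(r['selected_mean_median']):.2f}, "
            f"{int(r['n_selected'])} grids)"
        )
    return g_best, "\n".join(notes)
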