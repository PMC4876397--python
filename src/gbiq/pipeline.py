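"""End-to-end workflows: colony quantification and tissue-section inference.

Two canonical chains, both driven by a single mandatory parameter (the grid
size g):

* colony: quantify -> Median_IQR filter on the counterstain -> mixture
  sub-classification of the nucleus-pure grids on the channel medians ->
  reporter(+)/(-) comparison (fold change, Brunner-Munzel test, densities).
* tissue: quantify -> Median_IQR filter -> k-means-suggested, BIC-fitted
  mixture on the factor medians -> additive-model inference of which factor
  predicts the target's decline, within the class expressing all factors.

`run_pipeline` wraps the colony chain behind a declarative RunConfig (the
CLI's `run` subcommand); the *_workflow functions are the library surface.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .filtering import FilterResult, median_iqr_filter
from .gam import PenalizedAdditiveModel, fit_gam
from .gridding import quantify
from .image_io import MultiChannelImage, read_channel, write_grid_matrix
from .mixture import GaussianMixtureBIC, suggest_k_kmeans
from .stats import BMTestResult, brunner_munzel, fold_change, kde, normalize_intensity

__all__ = [
    "RunConfig",
    "ColonyResult",
    "TissueResult",
    "colony_workflow",
    "tissue_workflow",
    "compare_groups",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# library workflows

@dataclass(frozen=True)
class ColonyResult:
    matrix: pd.DataFrame
    filter_result: FilterResult
    subclassifier: GaussianMixtureBIC
    classified: pd.DataFrame          # filtered grids + cluster/designation
    positive_cluster: int
    fold_change: float
    bm_test: BMTestResult | None
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class TissueResult:
    matrix: pd.DataFrame
    filter_result: FilterResult
    suggested_k: int
    classifier: GaussianMixtureBIC
    classified: pd.DataFrame
    target_class: int
    gam: PenalizedAdditiveModel
    factor_names: tuple[str, str]     # the two candidate regressors


def compare_groups(a, b, bit_depth: int = 8, bandwidth: float = 0.05):
    """Brunner-Munzel test + fold change + normalized KDE curves for a vs b."""
    bm = brunner_munzel(a, b)
    fc = fold_change(a, b)
    curves = {
        "a": kde(normalize_intensity(a, bit_depth), bandwidth),
        "b": kde(normalize_intensity(b, bit_depth), bandwidth),
    }
    return bm, fc, curves


def colony_workflow(
    images: MultiChannelImage | list[MultiChannelImage],
    counterstain: str,
    reporter: str,
    marker: str,
    g: int = 20,
    seed: int = 1,
    filter_k_range: tuple[int, int] = (1, 9),
    subclass_k_range: tuple[int, int] = (2, 4),
    n_init: int = 10,
) -> ColonyResult:
    """Quantify, filter, sub-classify and compare reporter subpopulations.

    The nucleus-pure grids surviving the Median_IQR filter are re-clustered
    on all channel medians; the sub-class with the highest mean reporter
    median is designated reporter(+), all others reporter(-). Returns the
    marker fold change reporter(+)/reporter(-) with its Brunner-Munzel test.
    """
    matrix = quantify(images, g)
    fres = median_iqr_filter(matrix, counterstain, k_range=filter_k_range, seed=seed)
    sel = fres.selected
    feat_names = [f"{c}_median" for c in (counterstain, reporter, marker)]
    feats = sel[feat_names].to_numpy()
    sub = GaussianMixtureBIC(
        k_range=subclass_k_range, random_state=seed + 1, n_init=n_init
    ).fit(feats, feature_names=feat_names)
    labels = sub.predict(feats)
    rep_idx = feat_names.index(f"{reporter}_median")
    # reporter(+) = the high group of a 2-means split over the cluster mean
    # reporter levels; the graded reporter population may span >1 cluster
    cl_means = sub.means_[:, rep_idx]
    if sub.k_ == 1:
        pos_clusters = np.array([0])
    else:
        order = np.argsort(cl_means)
        gaps = np.diff(cl_means[order])
        cut = int(np.argmax(gaps)) + 1
        pos_clusters = order[cut:]
    is_pos = np.isin(labels, pos_clusters)
    classified = sel.copy()
    classified["cluster"] = labels
    classified["designation"] = np.where(is_pos, "reporter(+)", "reporter(-)")

    mk = f"{marker}_median"
    a = classified.loc[is_pos, mk].to_numpy()
    b = classified.loc[~is_pos, mk].to_numpy()
    fc = fold_change(a, b) if len(a) and len(b) else np.nan
    try:
        bm = brunner_munzel(a, b) if len(a) >= 2 and len(b) >= 2 else None
    except ZeroDivisionError:
        bm = None
    return ColonyResult(
        matrix=matrix, filter_result=fres, subclassifier=sub,
        classified=classified,
        positive_cluster=int(pos_clusters[np.argmax(cl_means[pos_clusters])]),
        fold_change=float(fc), bm_test=bm, n_positive=len(a), n_negative=len(b),
    )


def tissue_workflow(
    images: MultiChannelImage | list[MultiChannelImage],
    counterstain: str,
    target: str,
    candidates: tuple[str, str],
    g: int = 16,
    seed: int = 1,
    filter_k_range: tuple[int, int] = (1, 9),
    k_max: int = 6,
    basis_size: int = 10,
    n_init: int = 10,
    thin_spacing: int = 2,
) -> TissueResult:
    """Tissue-section chain ending in additive-model regulatory inference.

    After filtering on the counterstain, grids are clustered on the three
    factor medians with the component count suggested by k-means (f(K)
    criterion) and the covariance family still chosen by BIC. The class with
    the highest combined candidate-factor expression (where all factors are
    present) feeds ``target ~ s(candidate_1) + s(candidate_2)``.

    Before the additive model, the target class is thinned to every
    ``thin_spacing``-th grid row and column: when nuclei are about as large
    as a grid or larger, adjacent grids resample the same nucleus, and such
    pseudo-replication overstates the effective sample size of the smooth-
    term tests. ``thin_spacing=1`` disables thinning.
    """
    matrix = quantify(images, g)
    fres = median_iqr_filter(matrix, counterstain, k_range=filter_k_range, seed=seed)
    sel = fres.selected
    factor_cols = [f"{c}_median" for c in (target, *candidates)]
    feats = sel[factor_cols].to_numpy()
    k = suggest_k_kmeans(feats, k_max=k_max, seed=seed)
    clf = GaussianMixtureBIC(
        k_range=(k, k), random_state=seed + 1, n_init=n_init
    ).fit(feats, feature_names=factor_cols)
    labels = clf.predict(feats)
    classified = sel.copy()
    classified["cluster"] = labels

    cand_idx = [factor_cols.index(f"{c}_median") for c in candidates]
    target_class = int(np.argmax(clf.means_[:, cand_idx].sum(axis=1)))
    sub = classified.loc[classified["cluster"] == target_class]
    if thin_spacing > 1:
        # checkerboard: no two kept grids share an edge
        sub = sub.loc[(sub["grid_row"] + sub["grid_col"]) % thin_spacing == 0]
    gam = fit_gam(
        sub[f"{target}_median"].to_numpy(),
        sub[[f"{c}_median" for c in candidates]].to_numpy(),
        basis_size=basis_size,
    )
    return TissueResult(
        matrix=matrix, filter_result=fres, suggested_k=k, classifier=clf,
        classified=classified, target_class=target_class, gam=gam,
        factor_names=candidates,
    )


# --------------------------------------------------------------------------
# config-driven run

@dataclass
class RunConfig:
    """Declarative description of one colony-pipeline run."""

    images: list[dict]                 # [{image_id, channels: {name: path}}]
    g: int
    counterstain: str
    reporter: str | None = None
    marker: str | None = None
    k_range: tuple[int, int] = (1, 9)
    seed: int = 1
    outdir: str = "gbiq_out"
    include_mean_sd: bool = False
    normalize: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid run config {path}: {exc}") from exc
        cfg.k_range = tuple(cfg.k_range)  # YAML lists -> tuple
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.images:
            raise ValueError("run config lists no images")
        for entry in self.images:
            for name, p in entry.get("channels", {}).items():
                if not Path(p).exists():
                    raise FileNotFoundError(
                        f"image {entry.get('image_id')!r} channel {name!r}: "
                        f"missing file {p}"
                    )
        if self.g < 2:
            raise ValueError("g must be >= 2")

    def load_images(self) -> list[MultiChannelImage]:
        out = []
        for entry in self.images:
            chans = tuple(
                read_channel(p, name) for name, p in entry["channels"].items()
            )
            out.append(MultiChannelImage(image_id=entry["image_id"], channels=chans))
        return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the colony pipeline over all configured images.

    Writes the grid matrix, the filter report (class stats + per-grid
    selection), the cluster report, the comparison statistics and a run log
    into ``config.outdir``. Raises on failure, leaving partial outputs
    alongside a FAILED marker.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"gbiq {__version__} on python {platform.python_version()}",
        f"seed={config.seed} g={config.g} k_range={config.k_range} "
        f"counterstain={config.counterstain} reporter={config.reporter} "
        f"marker={config.marker} include_mean_sd={config.include_mean_sd} "
        f"normalize={config.normalize}",
        "defaults: quantile=linear-interpolation, EM restarts=10, "
        "EM tol=1e-8, BIC=-2LL+p*ln(n) minimized, strict filter criteria",
    ]
    stage = "load-images"
    try:
        images = config.load_images()
        stage = "quantify"
        matrix = quantify(images, config.g, include_mean_sd=config.include_mean_sd)
        write_grid_matrix(matrix, outdir / "grid_matrix.csv")
        log_lines.append(f"quantify: {len(matrix)} grid records")

        stage = "filter"
        fres = median_iqr_filter(
            matrix, config.counterstain, k_range=config.k_range, seed=config.seed
        )
        write_grid_matrix(fres.matrix, outdir / "grid_matrix_filtered.csv")
        fres.class_stats.to_csv(outdir / "filter_report.csv", index=False)
        log_lines.append(
            f"filter: selected classes {fres.selected_classes} "
            f"({len(fres.selected)} grids), fallback={fres.fallback_used}"
        )

        if config.reporter and config.marker:
            stage = "classify"
            res = colony_workflow(
                images, config.counterstain, config.reporter, config.marker,
                g=config.g, seed=config.seed, filter_k_range=config.k_range,
            )
            write_grid_matrix(res.classified, outdir / "cluster_report.csv")
            stage = "compare"
            stats = {
                "fold_change": res.fold_change,
                "n_reporter_pos": res.n_positive,
                "n_reporter_neg": res.n_negative,
            }
            if res.bm_test is not None:
                stats.update(
                    bm_statistic=res.bm_test.statistic, bm_df=res.bm_test.df,
                    bm_p_value=res.bm_test.p_value, bm_p_hat=res.bm_test.p_hat,
                )
            pd.DataFrame([stats]).to_csv(outdir / "stats.csv", index=False)
            log_lines.append(f"compare: {stats}")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        raise
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return {p.name: p for p in outdir.iterdir()}
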