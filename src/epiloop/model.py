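"""Model / Results front-end, statsmodels style.

:class:`PromoterExpressionModel` fits the boosted-tree predictor of RNA
log2 fold change from the seven promoter epigenetic features, with
10-fold cross-validation, exact Shapley attribution, error-aware
filtering and module discovery; its :meth:`~PromoterExpressionModel.fit`
returns a :class:`PromoterExpressionResults` carrying estimates and
diagnostics with a ``summary()`` table.

:class:`LoopArchitectureModel` runs the Hi-ChIP loop analytics
(inclusion filtering, anchor/loop classification, de-novo contact
detection, size/expression/effect-size statistics) against an
annotation context, returning :class:`LoopArchitectureResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import loops as lp
from .gbm import BoostedForest, CvResult, GbmParams, cross_validate, fit_gbm
from .modules import (FilterCriteria, ModuleAssignment, cluster_shap,
                      filter_transcripts, rank_cluster_features)
from .shapley import (ShapMatrix, mean_abs_shap_by_direction,
                      sample_background, shap_matrix)
from .synthetic import FEATURES, PromoterFeatureTable


class PromoterExpressionModel:
    """Predict promoter expression change from epigenetic feature changes.

    Parameters
    ----------
    table:
        A :class:`~epiloop.synthetic.PromoterFeatureTable` (or use
        :meth:`from_dataframe`).
    params:
        Boosting hyperparameters; defaults to the desk-scale profile
        (500 estimators) — pass ``GbmParams()`` for the full 10 000-
        estimator contract.
    background_size:
        Number of seeded training rows used as the interventional
        SHAP background.
    """

    def __init__(self, table: PromoterFeatureTable,
                 params: GbmParams | None = None,
                 background_size: int = 256):
        self.table = table
        self.params = params or GbmParams.desk()
        self.background_size = background_size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs
                       ) -> "PromoterExpressionModel":
        return cls(PromoterFeatureTable(df), **kwargs)

    def fit(self, cross_validate_folds: bool = True, explain: bool = True,
            criteria: FilterCriteria | None = None,
            k_up: int = 4, k_down: int = 3) -> "PromoterExpressionResults":
        """Train, cross-validate, explain and cluster.

        SHAP values and module clustering are computed on the
        error-aware kept set (|lfc| > 0.5, |error| < 0.5).
        """
        X = self.table.X()
        y = self.table.y()
        ids = self.table.df["transcript_id"].to_numpy()
        criteria = criteria or FilterCriteria()

        forest = fit_gbm(X, y, self.params,
                         feature_names=self.table.feature_names)
        cv = None
        kept = unexplained = None
        shap = assignment = None
        if cross_validate_folds:
            cv = cross_validate(X, y, self.params, transcript_ids=ids,
                                feature_names=self.table.feature_names)
            kept, unexplained = filter_transcripts(y, cv.error, criteria)
        if explain:
            rows = kept if kept is not None else np.ones(len(y), dtype=bool)
            background = sample_background(X, self.background_size,
                                           seed=self.params.seed)
            shap = shap_matrix(forest, X[rows], background,
                               transcript_ids=ids[rows])
            if rows.sum() >= max(k_up, k_down) + 1:
                assignment = cluster_shap(shap, k_up=k_up, k_down=k_down)
        return PromoterExpressionResults(
            model=self, forest=forest, cv=cv, criteria=criteria,
            kept_mask=kept, unexplained_mask=unexplained,
            shap=shap, modules=assignment)


@dataclass
class PromoterExpressionResults:
    """Fitted promoter-expression model with diagnostics."""

    model: PromoterExpressionModel
    forest: BoostedForest
    cv: CvResult | None
    criteria: FilterCriteria
    kept_mask: np.ndarray | None
    unexplained_mask: np.ndarray | None
    shap: ShapMatrix | None
    modules: ModuleAssignment | None
    _ranking: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum()) if self.kept_mask is not None else 0

    @property
    def n_unexplained(self) -> int:
        return (int(self.unexplained_mask.sum())
                if self.unexplained_mask is not None else 0)

    def cluster_feature_ranking(self) -> pd.DataFrame:
        if self.modules is None or self.shap is None:
            raise ValueError("fit without clustering")
        if self._ranking is None:
            self._ranking = rank_cluster_features(self.modules, self.shap)
        return self._ranking

    def shap_summary(self) -> pd.DataFrame:
        if self.shap is None:
            raise ValueError("fit without SHAP explanation")
        return mean_abs_shap_by_direction(self.shap)

    def well_predicted_fraction(self) -> float:
        """Of variably expressed transcripts (|lfc| above threshold),
        the fraction with |error| below threshold."""
        if self.cv is None:
            raise ValueError("fit without cross-validation")
        y = self.model.table.y()
        variable = np.abs(y) > self.criteria.min_abs_lfc
        if not variable.any():
            return float("nan")
        ok = np.abs(self.cv.error) < self.criteria.max_abs_error
        return float((variable & ok).sum() / variable.sum())

    def summary(self) -> str:
        lines = ["Promoter expression model"
                 "\n=========================",
                 f"promoters: {len(self.model.table)}",
                 f"features:  {', '.join(self.forest.feature_names)}",
                 f"estimators: {len(self.forest.trees)}  "
                 f"(lr={self.forest.learning_rate}, "
                 f"max_leaves={self.model.params.max_leaves})"]
        if self.cv is not None:
            lines += [
                f"CV r2 (Pearson^2): {self.cv.r2_pearson:.3f}",
                f"CV r2 (coef. of determination): {self.cv.r2_cod:.3f}",
                f"CV RMSE: {self.cv.rmse:.3f}",
                f"kept (|lfc|>{self.criteria.min_abs_lfc}, "
                f"|err|<{self.criteria.max_abs_error}): {self.n_kept}",
                f"unexplained: {self.n_unexplained}",
                f"well-predicted fraction: "
                f"{self.well_predicted_fraction():.3f}",
            ]
        if self.modules is not None:
            counts = self.modules.df["cluster"].value_counts().sort_index()
            tops = {c: r[0] for c, r in
                    self.modules.feature_ranking.items()}
            for cluster, n in counts.items():
                lines.append(f"  cluster {cluster}: n={n}, "
                             f"top feature {tops[cluster]}")
        return "\n".join(lines)

    # --- plotting ----------------------------------------------------------

    def plot_dependence(self, feature: str, ax=None):
        from .plotting import shap_dependence_plot
        X = self.model.table.df.loc[self.kept_mask, FEATURES] \
            if self.kept_mask is not None else self.model.table.df[FEATURES]
        return shap_dependence_plot(self.shap, X, feature, ax=ax)

    def plot_waterfall(self, transcript_id: str, ax=None):
        from .plotting import waterfall_plot
        idx = list(self.shap.df["transcript_id"]).index(transcript_id)
        return waterfall_plot(self.shap.row(idx), ax=ax)


# ---------------------------------------------------------------------------
# loop architecture


class LoopArchitectureModel:
    """Annotate and compare two-condition Hi-ChIP loop sets.

    Built from an unfiltered :class:`~epiloop.loops.LoopSet` with
    replicate counts, an :class:`~epiloop.loops.AnnotationContext`, and
    optionally an anchor-signal table (chrom, start, end, group,
    signal) and a transcript log2FC series for expression shifts.
    """

    def __init__(self, loopset: lp.LoopSet, context: lp.AnnotationContext,
                 anchor_signal: pd.DataFrame | None = None,
                 tss_lfc: pd.Series | None = None):
        self.loopset = loopset
        self.context = context
        self.anchor_signal = anchor_signal
        self.tss_lfc = tss_lfc

    def fit(self) -> "LoopArchitectureResults":
        retained = lp.filter_loops(self.loopset)
        classes = lp.classify_loops(retained, self.context)

        # condition-specific vs. common among retained loops
        mask_b = np.zeros(len(retained), dtype=bool)
        mask_w = np.zeros(len(retained), dtype=bool)
        for cond, mask in (("beige", mask_b), ("white", mask_w)):
            r1, r2 = lp.CONDITIONS[cond]
            a = retained.df[r1].to_numpy()
            b = retained.df[r2].to_numpy()
            mask |= (a > 6) & (b > 6) & (a + b > 18)
        beige_only = mask_b & ~mask_w
        common = mask_b & mask_w
        beige_set = lp.LoopSet(retained.df[beige_only], retained.bin_size)
        common_set = lp.LoopSet(retained.df[common], retained.bin_size)

        de_novo_set, de_novo_flags, de_novo_prop = lp.de_novo_anchors(
            beige_set, common_set)
        sizes = lp.loop_sizes(retained)
        b_sizes = lp.loop_sizes(beige_set)
        size_stats = None
        if de_novo_flags.any() and (~de_novo_flags).any():
            size_stats = lp.size_comparison(b_sizes[de_novo_flags],
                                            b_sizes[~de_novo_flags])
        overlap = None
        if self.context.dars is not None and \
                self.context.diff_h3k27ac is not None and len(beige_set):
            overlap = lp.anchor_overlap_proportions(beige_set, self.context)
        cohend = None
        if self.anchor_signal is not None:
            vals = {g: v.to_numpy() for g, v in
                    self.anchor_signal.groupby("group")["signal"]}
            if "beige_unique" in vals and "common" in vals:
                cohend = lp.cohens_d(vals["beige_unique"], vals["common"])
            elif len(vals) == 2:
                a, b = (vals[g] for g in sorted(vals))
                cohend = lp.cohens_d(a, b)
        expression = None
        if self.tss_lfc is not None and len(beige_set) and len(common_set):
            expression = lp.loop_expression_shift(
                {"beige": beige_set, "common": common_set},
                self.context, self.tss_lfc)
        return LoopArchitectureResults(
            model=self, retained=retained, classes=classes,
            beige_mask=beige_only, common_mask=common,
            de_novo_anchor_set=de_novo_set, de_novo_flags=de_novo_flags,
            de_novo_proportion=de_novo_prop, sizes=sizes,
            size_stats=size_stats, overlap_proportions=overlap,
            anchor_cohens_d=cohend, expression=expression)


@dataclass
class LoopArchitectureResults:
    model: LoopArchitectureModel
    retained: lp.LoopSet
    classes: pd.DataFrame
    beige_mask: np.ndarray
    common_mask: np.ndarray
    de_novo_anchor_set: set
    de_novo_flags: np.ndarray
    de_novo_proportion: float
    sizes: np.ndarray
    size_stats: dict | None
    overlap_proportions: dict | None
    anchor_cohens_d: float | None
    expression: pd.DataFrame | None

    @property
    def n_input(self) -> int:
        return len(self.model.loopset)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def class_table(self) -> pd.Series:
        """Proportions of the five loop classes (degenerate excluded)."""
        good = self.classes.loc[~self.classes["degenerate"], "loop_class"]
        return good.value_counts(normalize=True).reindex(
            lp.LOOP_CLASSES, fill_value=0.0)

    def summary(self) -> str:
        lines = ["Loop architecture"
                 "\n=================",
                 f"input loops: {self.n_input}",
                 f"retained: {self.n_retained} "
                 f"(dropped {self.n_input - self.n_retained})",
                 f"beige-specific: {int(self.beige_mask.sum())}, "
                 f"common: {int(self.common_mask.sum())}",
                 f"de-novo beige loops: {self.de_novo_proportion:.1%} "
                 f"({len(self.de_novo_anchor_set)} novel anchor bins)"]
        for cls, frac in self.class_table().items():
            lines.append(f"  {cls}: {frac:.1%}")
        if self.size_stats is not None:
            lines.append(
                f"de-novo vs common-anchor beige loop size: medians "
                f"{self.size_stats['median_a']:.0f} / "
                f"{self.size_stats['median_b']:.0f} bp, "
                f"rank-sum p={self.size_stats['pvalue']:.2e}")
        if self.overlap_proportions is not None:
            o = self.overlap_proportions
            lines.append(f"beige loops with DAR/diffK27 at anchors: "
                         f"both {o['both']:.1%}, DAR-only "
                         f"{o['dar_only']:.1%}, diffK27-only "
                         f"{o['diffk27_only']:.1%}, neither "
                         f"{o['neither']:.1%}")
        if self.anchor_cohens_d is not None:
            lines.append(f"anchor signal Cohen's D (beige-unique vs "
                         f"common): {self.anchor_cohens_d:.2f}")
        if self.expression is not None:
            for g, row in self.expression.iterrows():
                lines.append(f"  {g} loop transcripts: n={int(row['n'])}, "
                             f"median lfc {row['median_lfc']:.2f}, "
                             f"signed-rank p={row['pvalue']:.2e}")
        return "\n".join(lines)
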