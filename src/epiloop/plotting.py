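"""Matplotlib views of SHAP summaries and loop statistics."""

from __future__ import annotations

import numpy as np

from .shapley import ShapExplanation, ShapMatrix, dependence_data, waterfall


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def shap_dependence_plot(shap: ShapMatrix, X, feature: str, ax=None):
    """Scatter of phi against the feature value, with a value histogram."""
    ax = _axes(ax)
    data = dependence_data(shap, X, feature)
    pairs = data["pairs"]
    ax.scatter(pairs["feature_value"], pairs["phi"], s=6, alpha=0.5)
    twin = ax.twinx()
    centers = (data["hist_edges"][:-1] + data["hist_edges"][1:]) / 2
    width = np.diff(data["hist_edges"])
    twin.bar(centers, data["hist_counts"], width=width, color="0.85",
             zorder=0)
    twin.set_yticks([])
    ax.set_zorder(twin.get_zorder() + 1)
    ax.patch.set_visible(False)
    ax.set_xlabel(f"{feature} log2FC")
    ax.set_ylabel("SHAP value (log2 units)")
    return ax


def waterfall_plot(explanation: ShapExplanation, ax=None):
    """Cumulative feature contributions from base value to prediction."""
    ax = _axes(ax)
    wf = waterfall(explanation)
    start = np.concatenate([[explanation.base_value],
                            wf["cumulative"].to_numpy()[:-1]])
    colors = ["#d62728" if v < 0 else "#2ca02c" for v in wf["phi"]]
    ax.barh(np.arange(len(wf))[::-1], wf["phi"], left=start, color=colors)
    ax.set_yticks(np.arange(len(wf))[::-1], wf["feature"])
    ax.axvline(explanation.base_value, ls=":", c="0.4")
    ax.axvline(explanation.prediction, ls="--", c="0.2")
    ax.set_xlabel("model output (log2 units)")
    ax.set_title(explanation.transcript_id)
    return ax


def loop_size_density(sizes_by_group: dict[str, np.ndarray], ax=None):
    """Log10 loop-size density per group."""
    ax = _axes(ax)
    for name, sizes in sizes_by_group.items():
        vals = np.log10(np.maximum(np.asarray(sizes, dtype=float), 1.0))
        ax.hist(vals, bins=40, density=True, histtype="step", label=name)
    ax.set_xlabel("log10 loop size (bp)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
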