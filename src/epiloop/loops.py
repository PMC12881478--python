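"""H3K27ac Hi-ChIP loop annotation and comparison.

Loops are pairs of 5-kb genomic bins ("anchors") with per-condition,
per-replicate interaction counts (white/beige, two replicates each).
This module implements the analytics applied to called loop sets:

* the count-based inclusion rule (both replicates of a condition above 6
  reads and that condition's total above 18),
* anchor classification into Promoter / Enhancer / Other from TSS-upstream
  windows and H3K4me3 / H3K27ac peak sets,
* loop classification from the unordered anchor-class pair,
* de-novo contact detection (beige-loop anchor bins absent from every
  common-loop anchor),
* loop size (nearest-edge gap), rank-based group comparisons, anchor
  overlap proportions and Cohen's D anchor-signal effect sizes.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

COUNT_COLUMNS = ["white_rep1", "white_rep2", "beige_rep1", "beige_rep2"]
CONDITIONS = {"white": ("white_rep1", "white_rep2"),
              "beige": ("beige_rep1", "beige_rep2")}

#: the five loop classes; Other–Other is degenerate and reported separately
LOOP_CLASSES = [
    "Enhancer-Enhancer", "Enhancer-Promoter", "Promoter-Promoter",
    "Enhancer-Other", "Promoter-Other",
]
_CLASS_RANK = {"Enhancer": 0, "Promoter": 1, "Other": 2}


@dataclass
class LoopSet:
    """A set of intrachromosomal loops with replicate counts.

    ``df`` holds BEDPE-style columns (chrom1, start1, end1, chrom2,
    start2, end2) plus the four count columns. Anchors are sorted on
    construction so that anchor1 precedes anchor2.
    """

    df: pd.DataFrame
    bin_size: int = 5000

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        if len(df):
            swap = (df["chrom1"] > df["chrom2"]) | (
                (df["chrom1"] == df["chrom2"]) & (df["start1"] > df["start2"])
            )
            if swap.any():
                for a, b in (("chrom1", "chrom2"), ("start1", "start2"),
                             ("end1", "end2")):
                    df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def anchor_frame(self) -> pd.DataFrame:
        """Long-format frame of both anchors (loop index, side, coords)."""
        parts = []
        for side in (1, 2):
            part = self.df[[f"chrom{side}", f"start{side}", f"end{side}"]]
            part = part.rename(columns={
                f"chrom{side}": "chrom", f"start{side}": "start",
                f"end{side}": "end"})
            part = part.assign(loop=np.arange(len(self.df)), side=side)
            parts.append(part)
        if not parts or not len(self.df):
            return pd.DataFrame(columns=["chrom", "start", "end", "loop", "side"])
        return pd.concat(parts, ignore_index=True)

    def anchor_bins(self) -> set[tuple[str, int]]:
        """Set of (chrom, start // bin_size) over both anchors."""
        bins = set()
        for side in (1, 2):
            chs = self.df[f"chrom{side}"].to_numpy()
            sts = self.df[f"start{side}"].to_numpy() // self.bin_size
            bins.update(zip(chs, sts.tolist()))
        return bins


@dataclass
class AnnotationContext:
    """Interval sets used to classify loop anchors.

    ``tss_windows`` are strand-aware 2-kb upstream windows (plus strand:
    [tss-2000, tss); minus strand: the genomic mirror [tss+1, tss+2001)).
    """

    tss_windows: pd.DataFrame
    h3k4me3_peaks: pd.DataFrame
    h3k27ac_peaks: pd.DataFrame
    dars: pd.DataFrame | None = None
    diff_h3k27ac: pd.DataFrame | None = None
    _trees: dict = field(default_factory=dict, repr=False)

    def tree(self, which: str) -> dict[str, IntervalTree]:
        if which not in self._trees:
            df = getattr(self, which)
            if df is None:
                raise ValueError(f"context has no '{which}' interval set")
            self._trees[which] = interval_trees(df)
        return self._trees[which]


def tss_upstream_windows(tss_table: pd.DataFrame, length: int = 2000
                         ) -> pd.DataFrame:
    """Strand-aware upstream windows from a TSS table.

    ``tss_table`` needs columns chrom, tss, strand, transcript_id.
    """
    tss = tss_table["tss"].to_numpy()
    strand = tss_table["strand"].to_numpy()
    bad = ~np.isin(strand, ["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand symbol(s): {set(strand[bad])}")
    start = np.where(strand == "+", np.maximum(0, tss - length), tss + 1)
    end = np.where(strand == "+", tss, tss + 1 + length)
    return pd.DataFrame({
        "chrom": tss_table["chrom"].to_numpy(),
        "start": start.astype(int), "end": end.astype(int),
        "name": tss_table["transcript_id"].to_numpy(),
        "strand": strand,
    })


def interval_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        tree = IntervalTree()
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if e > s:
                tree.addi(int(s), int(e))
        trees[str(chrom)] = tree
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom: Iterable, start, end
              ) -> np.ndarray:
    """≥1 bp overlap of each query interval with any tree interval."""
    chrom = np.asarray(chrom)
    start = np.asarray(start)
    end = np.asarray(end)
    out = np.zeros(len(chrom), dtype=bool)
    for i in range(len(chrom)):
        tree = trees.get(str(chrom[i]))
        if tree is not None and tree.overlaps(int(start[i]), int(end[i])):
            out[i] = True
    return out


# ---------------------------------------------------------------------------
# inclusion filtering


def inclusion_mask(loops: LoopSet) -> np.ndarray:
    """Boolean mask of loops passing the count-inclusion rule.

    A loop is retained iff, in at least one condition, both replicates
    exceed 6 reads and the condition total exceeds 18 (strict
    inequalities).
    """
    df = loops.df
    counts = df[COUNT_COLUMNS].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative loop counts")
    mask = np.zeros(len(df), dtype=bool)
    for r1, r2 in CONDITIONS.values():
        a = df[r1].to_numpy()
        b = df[r2].to_numpy()
        mask |= (a > 6) & (b > 6) & (a + b > 18)
    return mask


def filter_loops(loops: LoopSet) -> LoopSet:
    """Retain loops passing :func:`inclusion_mask`."""
    return LoopSet(loops.df[inclusion_mask(loops)], loops.bin_size)


# ---------------------------------------------------------------------------
# anchor / loop classification


def classify_anchors(anchors: pd.DataFrame, context: AnnotationContext
                     ) -> np.ndarray:
    """Classify anchors as Promoter / Enhancer / Other.

    Promoter: overlaps a TSS-upstream window AND a H3K4me3 peak.
    Enhancer: otherwise, overlaps a H3K27ac peak. Precedence
    Promoter > Enhancer.
    """
    ch, st, en = anchors["chrom"], anchors["start"], anchors["end"]
    at_tss = _overlaps(context.tree("tss_windows"), ch, st, en)
    at_k4 = _overlaps(context.tree("h3k4me3_peaks"), ch, st, en)
    at_k27 = _overlaps(context.tree("h3k27ac_peaks"), ch, st, en)
    out = np.where(at_tss & at_k4, "Promoter",
                   np.where(at_k27, "Enhancer", "Other"))
    return out


def classify_anchor(chrom: str, start: int, end: int,
                    context: AnnotationContext) -> str:
    frame = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
    return str(classify_anchors(frame, context)[0])


def loop_class_label(class1: str, class2: str) -> str:
    """Unordered anchor-class pair → loop class label."""
    a, b = sorted((class1, class2), key=_CLASS_RANK.__getitem__)
    return f"{a}-{b}"


def classify_loops(loops: LoopSet, context: AnnotationContext
                   ) -> pd.DataFrame:
    """Per-loop anchor classes, loop class and degenerate flag."""
    df = loops.df
    c1 = classify_anchors(df.rename(columns={
        "chrom1": "chrom", "start1": "start", "end1": "end"}), context)
    c2 = classify_anchors(df.rename(columns={
        "chrom2": "chrom", "start2": "start", "end2": "end"}), context)
    labels = [loop_class_label(a, b) for a, b in zip(c1, c2)]
    out = pd.DataFrame({
        "anchor1_class": c1, "anchor2_class": c2, "loop_class": labels,
    })
    out["degenerate"] = out["loop_class"] == "Other-Other"
    return out


# ---------------------------------------------------------------------------
# de-novo contacts


def de_novo_anchors(beige: LoopSet, common: LoopSet
                    ) -> tuple[set[tuple[str, int]], np.ndarray, float]:
    """De-novo beige anchors, per-loop flags and the de-novo proportion.

    An anchor of a beige loop is de novo iff its bin id occurs in no
    common-loop anchor; a loop is de novo iff at least one of its
    anchors is.
    """
    if beige.bin_size != common.bin_size:
        raise ValueError("loop sets have different bin sizes")
    common_bins = common.anchor_bins()
    bs = beige.bin_size
    flags = np.zeros(len(beige), dtype=bool)
    novel: set[tuple[str, int]] = set()
    df = beige.df
    for side in (1, 2):
        chs = df[f"chrom{side}"].to_numpy()
        sts = df[f"start{side}"].to_numpy() // bs
        for i, key in enumerate(zip(chs, sts.tolist())):
            if key not in common_bins:
                novel.add(key)
                flags[i] = True
    proportion = float(flags.mean()) if len(beige) else float("nan")
    return novel, flags, proportion


# ---------------------------------------------------------------------------
# size and signal statistics


def loop_sizes(loops: LoopSet) -> np.ndarray:
    """Loop size = minimum distance between anchors (nearest-edge gap)."""
    df = loops.df
    if len(df) and (df["chrom1"] != df["chrom2"]).any():
        raise ValueError("interchromosomal loop has no size")
    gap = df["start2"].to_numpy() - df["end1"].to_numpy()
    return np.maximum(0, gap)


def loop_size(chrom1, start1, end1, chrom2, start2, end2) -> int:
    """Scalar loop size for a single anchor pair."""
    if chrom1 != chrom2:
        raise ValueError("interchromosomal loop has no size")
    if start1 > start2:
        (start1, end1), (start2, end2) = (start2, end2), (start1, end1)
    return max(0, start2 - end1)


def size_comparison(sizes_a: np.ndarray, sizes_b: np.ndarray) -> dict:
    """Medians plus a two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for small tie-free samples (n ≤ 20 per
    group), tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
        "statistic": float(res.statistic), "pvalue": float(res.pvalue),
        "method": method, "n_a": len(a), "n_b": len(b),
    }


def associated_transcripts(loops: LoopSet, context: AnnotationContext
                           ) -> list[str]:
    """Transcripts whose TSS-upstream window overlaps any loop anchor."""
    anchors = loops.anchor_frame()
    trees = interval_trees(anchors)
    win = context.tss_windows
    hit = _overlaps(trees, win["chrom"], win["start"], win["end"])
    return [str(t) for t in win.loc[hit, "name"]]


def loop_expression_shift(loops_by_group: Mapping[str, LoopSet],
                          context: AnnotationContext,
                          lfc: pd.Series,
                          paired: bool = False) -> pd.DataFrame:
    """Expression change of loop-associated transcripts, per loop group.

    ``lfc`` is indexed by transcript id (RNA log2 fold change, beige over
    white). For each group the associated transcripts' lfc values are
    tested against zero with a two-sided Wilcoxon signed-rank test; with
    ``paired=True`` the groups' common transcripts are compared pairwise
    instead (first two groups).
    """
    vectors: dict[str, pd.Series] = {}
    rows = []
    for name, loops in loops_by_group.items():
        tids = [t for t in associated_transcripts(loops, context)
                if t in lfc.index]
        if not tids:
            raise ValueError(f"no associated transcripts for group '{name}'")
        vals = lfc.loc[sorted(set(tids))]
        vectors[name] = vals
        res = stats.wilcoxon(vals.to_numpy(), alternative="two-sided")
        rows.append({"group": name, "n": len(vals),
                     "median_lfc": float(vals.median()),
                     "pvalue": float(res.pvalue)})
    out = pd.DataFrame(rows).set_index("group")
    if paired:
        names = list(vectors)
        if len(names) >= 2:
            a, b = vectors[names[0]], vectors[names[1]]
            shared = a.index.intersection(b.index)
            if len(shared) >= 5:
                res = stats.wilcoxon(a.loc[shared].to_numpy(),
                                     b.loc[shared].to_numpy(),
                                     alternative="two-sided")
                out.attrs["paired_pvalue"] = float(res.pvalue)
    out.attrs["vectors"] = vectors
    return out


def anchor_overlap_proportions(loops: LoopSet, context: AnnotationContext
                               ) -> dict[str, float]:
    """Proportions of loops with DARs and/or differential H3K27ac peaks
    at either anchor (four disjoint categories summing to 1)."""
    if context.dars is None or context.diff_h3k27ac is None:
        raise ValueError("context lacks DAR and/or differential-H3K27ac sets")
    df = loops.df
    dar = np.zeros(len(df), dtype=bool)
    diff = np.zeros(len(df), dtype=bool)
    for side in (1, 2):
        ch = df[f"chrom{side}"]
        st = df[f"start{side}"]
        en = df[f"end{side}"]
        dar |= _overlaps(context.tree("dars"), ch, st, en)
        diff |= _overlaps(context.tree("diff_h3k27ac"), ch, st, en)
    n = max(len(df), 1)
    return {
        "both": float((dar & diff).sum() / n),
        "dar_only": float((dar & ~diff).sum() / n),
        "diffk27_only": float((~dar & diff).sum() / n),
        "neither": float((~dar & ~diff).sum() / n),
    }


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Cohen's D with the pooled standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


#: Cohen's D applied to signal values at two anchor groups
anchor_signal_effect = cohens_d
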