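"""Promoter windows and per-promoter signal summarisation.

Promoters are the window TSS −2 kb / +300 bp in transcription
orientation (reflected genomically on the minus strand), 0-based
half-open, clamped at position 0. Normalised signal tracks (RPGC-like
coverage over non-overlapping intervals) are summarised as the
length-weighted mean over each window, and condition contrasts are
expressed as log2((beige + pc) / (white + pc)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UPSTREAM = 2000
DOWNSTREAM = 300


def promoter_windows(tss_table: pd.DataFrame) -> pd.DataFrame:
    """One TSS −2 kb / +300 bp window per transcript.

    ``tss_table`` needs columns chrom, tss, strand, transcript_id. Plus
    strand → [tss−2000, tss+300); minus strand → [tss−300, tss+2000);
    starts clamp at 0.
    """
    tss = tss_table["tss"].to_numpy()
    if (tss < 0).any():
        raise ValueError("negative TSS coordinate")
    strand = tss_table["strand"].to_numpy()
    bad = ~np.isin(strand, ["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand symbol(s): {set(strand[bad])}")
    plus = strand == "+"
    start = np.where(plus, tss - UPSTREAM, tss - DOWNSTREAM)
    end = np.where(plus, tss + DOWNSTREAM, tss + UPSTREAM)
    return pd.DataFrame({
        "chrom": tss_table["chrom"].to_numpy(),
        "start": np.maximum(0, start).astype(int),
        "end": end.astype(int),
        "strand": strand,
        "tss": tss,
        "transcript_id": tss_table["transcript_id"].to_numpy(),
    })


def summarize_signal(track: pd.DataFrame, windows: pd.DataFrame
                     ) -> np.ndarray:
    """Length-weighted mean track value over each window.

    ``track`` is bedGraph-like (chrom, start, end, value) with
    non-overlapping intervals per chromosome; windows without any
    overlapping interval score 0. Uncovered bases contribute value 0 to
    the mean (the mean is taken over the full window length).
    """
    if (track["value"] < 0).any():
        raise ValueError("signal values must be non-negative")
    out = np.zeros(len(windows))
    by_chrom = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        by_chrom[str(chrom)] = (sub["start"].to_numpy(),
                                sub["end"].to_numpy(),
                                sub["value"].to_numpy())
    missing: set[str] = set()
    chroms = windows["chrom"].to_numpy()
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    for i in range(len(windows)):
        key = str(chroms[i])
        if key not in by_chrom:
            missing.add(key)
            continue
        ts, te, tv = by_chrom[key]
        w0, w1 = starts[i], ends[i]
        if w1 <= w0:
            continue
        lo = np.searchsorted(te, w0, side="right")
        hi = np.searchsorted(ts, w1, side="left")
        if hi <= lo:
            continue
        ov = (np.minimum(te[lo:hi], w1) - np.maximum(ts[lo:hi], w0))
        out[i] = float((ov * tv[lo:hi]).sum()) / (w1 - w0)
    if missing:
        logger.warning("windows on chromosome(s) absent from track: %s",
                       sorted(missing))
    return out


def log2fc_features(beige_summary: pd.DataFrame, white_summary: pd.DataFrame,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-track log2((beige + pc) / (white + pc)) feature columns.

    Both summaries are indexed identically (one row per promoter window)
    with one column per track.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if list(beige_summary.columns) != list(white_summary.columns) or \
            len(beige_summary) != len(white_summary):
        raise ValueError("summaries cover different windows or tracks")
    b = beige_summary.to_numpy(dtype=float)
    w = white_summary.to_numpy(dtype=float)
    if (b < 0).any() or (w < 0).any():
        raise ValueError("negative signal values")
    feats = np.log2((b + pseudocount) / (w + pseudocount))
    return pd.DataFrame(feats, columns=beige_summary.columns,
                        index=beige_summary.index)


def deg_filter(gene_table: pd.DataFrame, max_fdr: float = 0.01,
               min_abs_lfc: float = 1.0) -> pd.DataFrame:
    """Differentially expressed genes: fdr < 0.01 and |log2fc| > 1.

    Strict inequalities; boundary rows are excluded.
    """
    for col in ("fdr", "log2fc"):
        if col not in gene_table.columns:
            raise ValueError(f"gene table lacks column '{col}'")
    keep = (gene_table["fdr"] < max_fdr) & \
        (gene_table["log2fc"].abs() > min_abs_lfc)
    return gene_table[keep]
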