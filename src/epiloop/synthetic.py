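"""Synthetic promoter-feature tables and two-condition loop fixtures.

The generators plant known, recoverable structure that emulates the
statistical shape of a white vs. beige adipogenesis study:

* promoters belong to five regulatory modules — an H3K27ac-driven
  "white" module, an H3K4me3-driven "beige" module, an
  accessibility-linear module, an enhancer-driven module whose
  expression change is invisible to promoter features, and a null
  module;
* two-condition Hi-ChIP-like loop sets with planted de-novo short-range
  beige loops, overdispersed (Gamma-Poisson) replicate counts and a
  planted anchor-signal effect size (Cohen's D).

All log2 fold changes are oriented beige over white, so white-specific
genes carry negative values. Every draw flows from a single seeded
generator: a fixed seed reproduces outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .loops import AnnotationContext, LoopSet, CONDITIONS

#: the seven per-promoter epigenetic feature tracks, in column order
FEATURES = ["H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "H3K36me3",
            "H3K9me3", "ATAC"]

MODULES = ["white_k27ac", "beige_k4me3", "atac_linear", "enhancer_driven",
           "null"]

_DEFAULT_PROPORTIONS = {
    "white_k27ac": 0.15, "beige_k4me3": 0.25, "atac_linear": 0.15,
    "enhancer_driven": 0.20, "null": 0.25,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Effect sizes are in log2 units; loop sizes in bp. ``anchor_signal_effect``
    is the planted Cohen's D between beige-unique and common anchor
    signal.
    """

    seed: int = 0
    n_promoters: int = 2000
    module_proportions: dict = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    effect_size: float = 1.5
    coef_atac: float = 0.8
    noise_sd: float = 0.4
    baseline_sd: float = 0.3
    n_chromosomes: int = 4
    chrom_length: int = 20_000_000
    n_common_loops: int = 2000
    n_beige_loops: int = 1000
    n_background_loops: int = 300
    frac_de_novo: float = 0.35
    bin_size: int = 5000
    beige_size_lognormal_mu: float = 11.0   # median ≈ 60 kb
    beige_size_lognormal_sigma: float = 0.8
    common_size_lognormal_mu: float = 12.2  # median ≈ 200 kb
    common_size_lognormal_sigma: float = 0.8
    count_mean_retained: float = 30.0
    count_mean_background: float = 3.0
    count_dispersion: float = 0.3
    anchor_signal_effect: float = 0.98

    def validate(self) -> None:
        total = sum(self.module_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"module proportions sum to {total}, not 1")
        if set(self.module_proportions) != set(MODULES):
            raise ValueError("module_proportions must name exactly "
                             f"{MODULES}")
        for name in ("n_promoters", "n_chromosomes", "chrom_length",
                     "n_common_loops", "n_beige_loops", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_de_novo <= 1.0:
            raise ValueError("frac_de_novo must lie in [0, 1]")
        if self.n_promoters < 10 * len(self.module_proportions):
            raise ValueError("n_promoters must be at least 10 per module")


@dataclass
class PromoterFeatureTable:
    """Per-transcript epigenetic feature changes and observed RNA change.

    ``df`` columns: transcript_id, the seven tracks of :data:`FEATURES`
    (log2 fold changes, beige over white), rna_log2fc, and optionally
    planted_module.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ["transcript_id", *FEATURES, "rna_log2fc"]
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table lacks columns: {missing}")
        if self.df["transcript_id"].duplicated().any():
            raise ValueError("transcript ids are not unique")
        numeric = self.df[[*FEATURES, "rna_log2fc"]]
        if numeric.isna().any().any():
            raise ValueError("feature table contains missing values")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> list[str]:
        return list(FEATURES)

    def X(self) -> np.ndarray:
        return self.df[FEATURES].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.df["rna_log2fc"].to_numpy(dtype=float)

    @property
    def planted(self) -> pd.Series | None:
        if "planted_module" in self.df:
            return self.df["planted_module"]
        return None


def generate_promoter_table(config: SyntheticConfig) -> PromoterFeatureTable:
    """Draw a promoter feature table with planted regulatory modules.

    All seven features start at Normal(0, baseline_sd); each module then
    shifts its driving feature by ±effect_size and sets the RNA change
    from its generative equation plus Normal(0, noise_sd) noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_promoters
    modules = rng.choice(MODULES, size=n,
                         p=[config.module_proportions[m] for m in MODULES])
    X = rng.normal(0.0, config.baseline_sd, size=(n, len(FEATURES)))
    eps = rng.normal(0.0, config.noise_sd, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    df = pd.DataFrame(X, columns=FEATURES)
    e = config.effect_size

    is_white = modules == "white_k27ac"
    df.loc[is_white, "H3K27ac"] -= e
    is_beige = modules == "beige_k4me3"
    df.loc[is_beige, "H3K4me3"] += e
    is_atac = modules == "atac_linear"
    df.loc[is_atac, "ATAC"] += signs[is_atac] * e

    rna = np.empty(n)
    rna[is_white] = (df.loc[is_white, "H3K27ac"]
                     + config.coef_atac * df.loc[is_white, "ATAC"]
                     + eps[is_white])
    rna[is_beige] = (df.loc[is_beige, "H3K4me3"]
                     + config.coef_atac * df.loc[is_beige, "ATAC"]
                     + eps[is_beige])
    rna[is_atac] = (config.coef_atac * df.loc[is_atac, "ATAC"]
                    + eps[is_atac])
    is_enh = modules == "enhancer_driven"
    rna[is_enh] = signs[is_enh] * e + eps[is_enh]
    is_null = modules == "null"
    rna[is_null] = eps[is_null]

    df.insert(0, "transcript_id", [f"TX{i:05d}" for i in range(n)])
    df["rna_log2fc"] = rna
    df["planted_module"] = modules
    return PromoterFeatureTable(df)


# ---------------------------------------------------------------------------
# loop fixture


@dataclass
class LoopFixture:
    """A generated two-condition loop study with its ground truth."""

    loops: LoopSet                 # all loops, including background
    context: AnnotationContext
    anchor_signal: pd.DataFrame    # chrom, start, end, group, signal
    truth: pd.DataFrame            # per-loop origin and planted de_novo flag
    tss_lfc: pd.Series             # planted expression change per transcript

    def __iter__(self):
        return iter((self.loops, self.context, self.anchor_signal))


def _gamma_poisson(rng, mean: float, size, dispersion: float) -> np.ndarray:
    """Overdispersed counts: Poisson with Gamma-distributed rate."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion, size=size)
    return rng.poisson(lam)


def _draw_counts(rng, cfg, n, beige_state, white_state) -> np.ndarray:
    """Draw 4 replicate counts per loop, rejecting until each condition
    matches its target state ('pass' or 'fail' of the inclusion rule)."""
    counts = np.zeros((n, 4), dtype=int)
    for cond, state, cols in (("white", white_state, (0, 1)),
                              ("beige", beige_state, (2, 3))):
        mean = (cfg.count_mean_retained if state == "pass"
                else cfg.count_mean_background)
        todo = np.ones(n, dtype=bool)
        for _ in range(1000):
            k = int(todo.sum())
            if k == 0:
                break
            draw = _gamma_poisson(rng, mean, (k, 2), cfg.count_dispersion)
            ok_rule = (draw[:, 0] > 6) & (draw[:, 1] > 6) & \
                (draw.sum(axis=1) > 18)
            accept = ok_rule if state == "pass" else ~ok_rule
            idx = np.flatnonzero(todo)[accept]
            counts[idx, cols[0]] = draw[accept, 0]
            counts[idx, cols[1]] = draw[accept, 1]
            todo[idx] = False
        else:
            raise RuntimeError("count rejection sampling did not converge")
    return counts


def generate_loop_fixture(config: SyntheticConfig) -> LoopFixture:
    """Generate loops, annotation context and anchor signal on a toy genome.

    Common loops are shared between conditions (counts pass the inclusion
    rule in both); beige loops pass only in beige; background loops fail
    in both. A Bernoulli(frac_de_novo) subset of beige loops receives at
    least one anchor bin absent from every common-loop anchor, and those
    de-novo loops draw their size from the (shorter) beige log-normal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bs = config.bin_size
    n_bins = config.chrom_length // bs
    if n_bins < 50:
        raise ValueError("chrom_length too small for the requested bin size")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    def gap_bins(mu, sigma, size):
        g = np.rint(rng.lognormal(mu, sigma, size=size) / bs).astype(int)
        return np.clip(g, 0, n_bins - 3)

    # --- common loops ------------------------------------------------------
    c_chr = rng.integers(0, len(chroms), size=config.n_common_loops)
    c_gap = gap_bins(config.common_size_lognormal_mu,
                     config.common_size_lognormal_sigma,
                     config.n_common_loops)
    c_a1 = np.array([rng.integers(0, n_bins - g - 1) for g in c_gap])
    c_a2 = c_a1 + 1 + c_gap

    common_bins: dict[str, set[int]] = {c: set() for c in chroms}
    for ci, a1, a2 in zip(c_chr, c_a1, c_a2):
        common_bins[chroms[ci]].update((int(a1), int(a2)))
    common_sorted = {c: np.array(sorted(v)) for c, v in common_bins.items()}

    # --- beige loops -------------------------------------------------------
    nb = config.n_beige_loops
    de_novo = rng.random(nb) < config.frac_de_novo
    b_chr = np.empty(nb, dtype=int)
    b_a1 = np.empty(nb, dtype=int)
    b_a2 = np.empty(nb, dtype=int)
    usable = [i for i, c in enumerate(chroms) if len(common_sorted[c]) >= 2]
    if not usable:
        raise ValueError("chrom_length too small: no chromosome carries "
                         "two common anchors")

    def fresh_bin(chrom, near, lo=0, hi=None):
        hi = n_bins if hi is None else hi
        taken = common_bins[chrom]
        b = int(np.clip(near, lo, hi - 1))
        for off in range(n_bins):
            for cand in (b + off, b - off):
                if lo <= cand < hi and cand not in taken:
                    return cand
        raise ValueError("chrom_length too small to place de-novo anchors")

    for i in range(nb):
        ci = usable[rng.integers(0, len(usable))]
        chrom = chroms[ci]
        bins = common_sorted[chrom]
        b_chr[i] = ci
        if de_novo[i]:
            g = int(gap_bins(config.beige_size_lognormal_mu,
                             config.beige_size_lognormal_sigma, 1)[0])
            if rng.random() < 0.5:
                a1 = int(bins[rng.integers(0, len(bins))])
            else:
                a1 = fresh_bin(chrom, rng.integers(0, n_bins - g - 1))
            a1 = min(a1, n_bins - g - 2)
            a2 = fresh_bin(chrom, a1 + 1 + g, lo=a1 + 1)
        else:
            g = int(gap_bins(config.common_size_lognormal_mu,
                             config.common_size_lognormal_sigma, 1)[0])
            j = rng.integers(0, max(1, len(bins) - 1))
            a1 = int(bins[j])
            later = bins[bins > a1]
            if len(later) == 0:
                a1 = int(bins[0])
                later = bins[bins > a1]
            a2 = int(later[np.argmin(np.abs(later - (a1 + 1 + g)))])
        b_a1[i], b_a2[i] = a1, a2

    # --- background loops (fail the inclusion rule everywhere) -------------
    nbg = config.n_background_loops
    g_chr = rng.integers(0, len(chroms), size=nbg)
    g_gap = gap_bins(config.common_size_lognormal_mu,
                     config.common_size_lognormal_sigma, nbg)
    g_a1 = np.array([rng.integers(0, n_bins - g - 1) for g in g_gap]) \
        if nbg else np.array([], dtype=int)
    g_a2 = g_a1 + 1 + g_gap

    counts = np.vstack([
        _draw_counts(rng, config, config.n_common_loops, "pass", "pass"),
        _draw_counts(rng, config, nb, "pass", "fail"),
        _draw_counts(rng, config, nbg, "fail", "fail"),
    ])
    origin = np.concatenate([
        np.repeat("common", config.n_common_loops),
        np.repeat("beige", nb),
        np.repeat("background", nbg),
    ])
    all_chr = np.concatenate([c_chr, b_chr, g_chr])
    all_a1 = np.concatenate([c_a1, b_a1, g_a1])
    all_a2 = np.concatenate([c_a2, b_a2, g_a2])

    df = pd.DataFrame({
        "chrom1": [chroms[i] for i in all_chr],
        "start1": all_a1 * bs, "end1": (all_a1 + 1) * bs,
        "chrom2": [chroms[i] for i in all_chr],
        "start2": all_a2 * bs, "end2": (all_a2 + 1) * bs,
        "name": [f"loop_{i:05d}" for i in range(len(all_a1))],
    })
    for j, col in enumerate(["white_rep1", "white_rep2",
                             "beige_rep1", "beige_rep2"]):
        df[col] = counts[:, j]
    loops = LoopSet(df, bin_size=bs)

    truth = pd.DataFrame({
        "name": df["name"], "origin": origin,
        "de_novo": np.concatenate([
            np.zeros(config.n_common_loops, dtype=bool), de_novo,
            np.zeros(nbg, dtype=bool)]),
    })

    # --- annotation context ------------------------------------------------
    anchor_keys = sorted({(chroms[c], int(a)) for c, a1, a2
                          in zip(all_chr, all_a1, all_a2)
                          for a in (a1, a2)})
    tss_rows, k4_rows, k27_rows = [], [], []
    lfc_ids, lfc_vals = [], []
    beige_promoter = {(chroms[c], int(a)) for c, a1, a2, o in
                      zip(all_chr, all_a1, all_a2, origin)
                      if o == "beige" for a in (a1, a2)}
    tx = 0
    for chrom, b in anchor_keys:
        start = b * bs
        u = rng.random()
        if u < 0.30:  # promoter anchor: TSS + H3K4me3 peak inside the bin
            tss = start + 2500
            tss_rows.append((chrom, tss, "+", f"TX{tx:05d}"))
            k4_rows.append((chrom, start + 1000, start + 2000))
            shift = 1.0 if (chrom, b) in beige_promoter else 0.0
            lfc_ids.append(f"TX{tx:05d}")
            lfc_vals.append(rng.normal(shift, 0.5))
            tx += 1
        if u < 0.85:  # H3K27ac peak (promoters usually carry one too)
            k27_rows.append((chrom, start + 500, start + 1500))
    tss_table = pd.DataFrame(tss_rows,
                             columns=["chrom", "tss", "strand",
                                      "transcript_id"])
    from .loops import tss_upstream_windows
    windows = tss_upstream_windows(tss_table)
    k4 = pd.DataFrame(k4_rows, columns=["chrom", "start", "end"])
    k27 = pd.DataFrame(k27_rows, columns=["chrom", "start", "end"])

    # DARs / differential H3K27ac peaks at beige anchors
    dar_rows, diff_rows = [], []
    for chrom, b in sorted(beige_promoter | {
            (chroms[c], int(a)) for c, a1, a2, o in
            zip(all_chr, all_a1, all_a2, origin) if o == "beige"
            for a in (a1, a2)}):
        start = b * bs
        if rng.random() < 0.45:
            dar_rows.append((chrom, start + 2000, start + 2600))
        if rng.random() < 0.30:
            diff_rows.append((chrom, start + 3000, start + 3400))
    context = AnnotationContext(
        tss_windows=windows, h3k4me3_peaks=k4, h3k27ac_peaks=k27,
        dars=pd.DataFrame(dar_rows, columns=["chrom", "start", "end"]),
        diff_h3k27ac=pd.DataFrame(diff_rows,
                                  columns=["chrom", "start", "end"]),
    )

    # --- anchor signal with planted Cohen's D ------------------------------
    # background anchors are excluded: the comparison is beige-unique vs.
    # common loop anchors
    common_keys = {(c, int(b)) for c, s in common_sorted.items() for b in s}
    signal_keys = sorted({(chroms[c], int(a)) for c, a1, a2, o
                          in zip(all_chr, all_a1, all_a2, origin)
                          if o != "background" for a in (a1, a2)})
    sig_rows = []
    for chrom, b in signal_keys:
        group = "common" if (chrom, b) in common_keys else "beige_unique"
        mean = 0.0 if group == "common" else config.anchor_signal_effect
        sig_rows.append((chrom, b * bs, (b + 1) * bs, group,
                         rng.normal(mean, 1.0)))
    anchor_signal = pd.DataFrame(
        sig_rows, columns=["chrom", "start", "end", "group", "signal"])

    tss_lfc = pd.Series(lfc_vals, index=pd.Index(lfc_ids, name="transcript_id"),
                        name="rna_log2fc")
    return LoopFixture(loops, context, anchor_signal, truth, tss_lfc)


# ---------------------------------------------------------------------------
# fixture round-trip


def write_fixtures(directory, table: PromoterFeatureTable | None = None,
                   loops: LoopSet | None = None,
                   context: AnnotationContext | None = None,
                   anchor_signal: pd.DataFrame | None = None) -> dict:
    """Write the generated objects to flat files; return a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def record(key, path):
        manifest[key] = path.name  # relative: manifests are location-free

    if table is not None:
        record("feature_table",
               eio.write_tsv(table.df, directory / "features.tsv"))
    if loops is not None:
        record("loops", eio.write_bedpe(loops.df, directory / "loops.bedpe"))
        manifest["bin_size"] = str(loops.bin_size)
    if context is not None:
        record("tss_windows", eio.write_bed(context.tss_windows,
                                            directory / "tss_windows.bed"))
        record("h3k4me3_peaks", eio.write_bed(
            context.h3k4me3_peaks, directory / "h3k4me3_peaks.bed"))
        record("h3k27ac_peaks", eio.write_bed(
            context.h3k27ac_peaks, directory / "h3k27ac_peaks.bed"))
        if context.dars is not None:
            record("dars", eio.write_bed(context.dars, directory / "dars.bed"))
        if context.diff_h3k27ac is not None:
            record("diff_h3k27ac", eio.write_bed(
                context.diff_h3k27ac, directory / "diff_h3k27ac.bed"))
    if anchor_signal is not None:
        record("anchor_signal",
               eio.write_tsv(anchor_signal, directory / "anchor_signal.tsv"))
    eio.write_json(manifest, directory / "manifest.json")
    return manifest


def load_feature_table(path) -> PromoterFeatureTable:
    return PromoterFeatureTable(eio.read_tsv(path))


def load_loopset(path, bin_size: int = 5000) -> LoopSet:
    return LoopSet(eio.read_bedpe(path), bin_size=bin_size)
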