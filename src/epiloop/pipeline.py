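"""End-to-end pipeline runs with config hashing and run manifests.

Two orchestrations: the expression pipeline (synthesize or load a
promoter feature table → train/CV → exact SHAP → error-aware filtering →
module clustering) and the loop pipeline (synthesize or load loops +
context → inclusion filter → classification → de-novo detection →
statistics). Outputs are flat TSV/BEDPE/JSON files; identical config and
seed reproduce identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as eio
from .gbm import GbmParams
from .loops import AnnotationContext, LoopSet, loop_sizes
from .model import LoopArchitectureModel, PromoterExpressionModel
from .modules import FilterCriteria, dendrogram_newick
from .synthetic import (SyntheticConfig, generate_loop_fixture,
                        generate_promoter_table, load_feature_table,
                        load_loopset, write_fixtures)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    The top-level ``seed`` propagates to every stochastic component
    (synthesis, CV fold shuffling, SHAP background sampling).
    """

    out_dir: str
    seed: int = 0
    feature_table: str | None = None   # TSV path; synthesized if None
    loops_path: str | None = None      # BEDPE path; synthesized if None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    gbm: GbmParams = field(default_factory=GbmParams.desk)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    k_up: int = 4
    k_down: int = 3
    background_size: int = 256
    bin_size: int = 5000
    verbosity: int = 1

    def __post_init__(self):
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
        self.gbm = dataclasses.replace(self.gbm, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # the output location must not affect the hash
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class _Stage:
    """Context manager tagging failures and logging elapsed time."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            raise PipelineError(f"[{self.name}] {exc}") from exc
        logger.info("stage %s finished in %.2fs", self.name, dt)
        return False


def _manifest(config: RunConfig, stage_counts: dict, files: list[str],
              out_dir: Path) -> dict:
    manifest = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "files": sorted(files),
    }
    eio.write_json(manifest, out_dir / "manifest.json")
    return manifest


def run_expression_pipeline(config: RunConfig) -> dict:
    """Synthesize/load features → train/CV → explain → modules."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    counts: dict[str, int] = {}

    with _Stage("features"):
        if config.feature_table is not None:
            table = load_feature_table(config.feature_table)
        else:
            table = generate_promoter_table(config.synthetic)
            eio.write_tsv(table.df, out / "features.tsv")
            files.append("features.tsv")
        counts["promoters"] = len(table)

    with _Stage("train"):
        model = PromoterExpressionModel(
            table, params=config.gbm,
            background_size=config.background_size)
        res = model.fit(criteria=config.criteria, k_up=config.k_up,
                        k_down=config.k_down)
        res.forest.save(out / "model.json")
        res.cv.save(out / "cv_result.tsv")
        files += ["model.json", "cv_result.tsv"]
        counts["filtered"] = res.n_kept
        counts["unexplained"] = res.n_unexplained

    with _Stage("explain"):
        res.shap.save(out / "shap_matrix.tsv")
        eio.write_tsv(res.shap_summary(), out / "shap_summary.tsv")
        files += ["shap_matrix.tsv", "shap_summary.tsv"]
        counts["explained"] = len(res.shap)

    with _Stage("modules"):
        if res.modules is not None:
            eio.write_tsv(res.modules.df, out / "module_assignment.tsv")
            eio.write_tsv(res.cluster_feature_ranking(),
                          out / "cluster_summary.tsv")
            files += ["module_assignment.tsv", "cluster_summary.tsv"]
            for name, Z in res.modules.linkage.items():
                labels = list(res.modules.df.loc[
                    res.modules.df["stratum"] == name, "transcript_id"])
                path = out / f"dendrogram_{name}.nwk"
                path.write_text(dendrogram_newick(Z, labels) + "\n")
                files.append(path.name)
            counts["clustered"] = len(res.modules.df)
        else:
            counts["clustered"] = 0
        (out / "summary.txt").write_text(res.summary() + "\n")
        files.append("summary.txt")

    return _manifest(config, counts, files, out)


def run_loop_pipeline(config: RunConfig) -> dict:
    """Synthesize/load loops + context → filter → annotate → statistics."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    counts: dict[str, int] = {}

    with _Stage("loops"):
        if config.loops_path is not None:
            loopset = load_loopset(config.loops_path,
                                   bin_size=config.bin_size)
            base = Path(config.loops_path).parent
            context = load_context(base)
            signal_path = base / "anchor_signal.tsv"
            signal = eio.read_tsv(signal_path) \
                if signal_path.exists() else None
            tss_lfc = None
        else:
            fixture = generate_loop_fixture(config.synthetic)
            loopset, context, signal = fixture.loops, fixture.context, \
                fixture.anchor_signal
            tss_lfc = fixture.tss_lfc
            write_fixtures(out / "fixtures", loops=loopset, context=context,
                           anchor_signal=signal)
            files.append("fixtures/manifest.json")
        counts["input_loops"] = len(loopset)

    with _Stage("annotate"):
        res = LoopArchitectureModel(loopset, context, anchor_signal=signal,
                                    tss_lfc=tss_lfc).fit()
        counts["retained"] = res.n_retained
        counts["dropped"] = res.n_input - res.n_retained
        counts["beige_specific"] = int(res.beige_mask.sum())
        counts["common"] = int(res.common_mask.sum())
        counts["de_novo_beige"] = int(res.de_novo_flags.sum())

    with _Stage("report"):
        eio.write_bedpe(res.retained.df, out / "retained_loops.bedpe")
        table = res.retained.df.reset_index(drop=True).copy()
        table = pd.concat([table, res.classes], axis=1)
        table["size"] = loop_sizes(res.retained)
        de_novo = np.zeros(len(table), dtype=bool)
        de_novo[np.flatnonzero(res.beige_mask)] = res.de_novo_flags
        table["de_novo"] = de_novo
        eio.write_tsv(table, out / "loop_table.tsv")
        stats = {
            "de_novo_proportion": res.de_novo_proportion,
            "class_proportions": res.class_table().to_dict(),
            "size_stats": res.size_stats,
            "overlap_proportions": res.overlap_proportions,
            "anchor_cohens_d": res.anchor_cohens_d,
        }
        eio.write_json(_jsonify(stats), out / "loop_stats.json")
        (out / "summary.txt").write_text(res.summary() + "\n")
        files += ["retained_loops.bedpe", "loop_table.tsv",
                  "loop_stats.json", "summary.txt"]

    return _manifest(config, counts, files, out)


def load_context(directory: Path) -> AnnotationContext:
    """Reassemble an annotation context from fixture BED files."""
    directory = Path(directory)

    def bed(name):
        path = directory / name
        return eio.read_bed(path) if path.exists() else None

    windows = bed("tss_windows.bed")
    k4 = bed("h3k4me3_peaks.bed")
    k27 = bed("h3k27ac_peaks.bed")
    if windows is None or k4 is None or k27 is None:
        raise FileNotFoundError(
            f"context BED files missing under {directory}")
    return AnnotationContext(
        tss_windows=windows, h3k4me3_peaks=k4, h3k27ac_peaks=k27,
        dars=bed("dars.bed"), diff_h3k27ac=bed("diff_h3k27ac.bed"))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
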