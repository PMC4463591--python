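"""End-to-end orchestration: simulate → preprocess → bands → classify.

``run_pipeline`` executes the whole analysis from one configuration and
writes every intermediate product (cohort, preprocessed spectra, band
tables, grade summaries, variance spectrum, PCA scores and loadings,
confusion matrices, metric report, run log) into a self-describing
directory.  Rerunning with the same configuration reproduces every
numeric output bit-identically.

``table1_demo`` feeds the packaged reference classification matrix (the
published 450-cell counts) through the metrics code — a worked example
that exercises the reporting conventions, including truncated-percent
rendering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BandDef, band_area_table, default_bands, grade_mean_spectra, \
    summarize_by_grade, variance_spectrum
from .classify import (
    ClassificationReport,
    ConfusionMatrix,
    loocv,
    mahal_fit,
    pca_fit,
    pca_transform,
    report,
    segmented_cv,
)
from .preprocess import PreprocessParams, run_chain
from .spectra import SpectrumSet, write_set, write_spectrum
from .synth import SynthConfig, default_config, generate_cohort

log = logging.getLogger("chondrospec")

# Published 450-cell classification matrix used by the worked example
# (rows = actual grade, columns = predicted grade, order I, II, III).
REFERENCE_CONFUSION = ConfusionMatrix(
    labels=("I", "II", "III"),
    counts=np.array([[150, 0, 0], [2, 145, 3], [0, 30, 120]]),
)


@dataclass(frozen=True)
class ClassifyConfig:
    n_components: int = 3
    covariance_policy: str = "per_class"
    segment_size: int = 10


@dataclass(frozen=True)
class RunConfig:
    synth: SynthConfig = field(default_factory=default_config)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    bands: tuple[BandDef, ...] = field(default_factory=default_bands)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    seed: int | None = None  # overrides synth.seed when given

    def resolved(self) -> "RunConfig":
        if self.seed is None:
            return self
        return replace(self, synth=replace(self.synth, seed=self.seed), seed=self.seed)


@dataclass
class PipelineResult:
    cells_raw: SpectrumSet
    backgrounds: SpectrumSet
    cells: SpectrumSet  # preprocessed
    band_table: pd.DataFrame
    grade_summary: pd.DataFrame
    explained_variance_fraction: np.ndarray
    scores: np.ndarray
    loo_confusion: ConfusionMatrix
    loo_report: ClassificationReport
    seg_confusion: ConfusionMatrix
    seg_report: ClassificationReport


def run_analysis(config: RunConfig) -> PipelineResult:
    """Run the full analysis in memory (no files written)."""
    cfg = config.resolved()
    log.info("generating cohort (seed=%d)", cfg.synth.seed)
    cells_raw, backgrounds = generate_cohort(cfg.synth)
    log.info("preprocessing %d spectra", len(cells_raw))
    cells = run_chain(cells_raw, backgrounds, cfg.preprocess)
    log.info("band quantification")
    table = band_area_table(cells, cfg.bands)
    summary = summarize_by_grade(table)
    pca = pca_fit(cells, cfg.classify.n_components)
    scores = pca_transform(pca, cells)
    log.info("leave-one-out cross-validation (n=%d)", len(cells))
    loo_cm = loocv(cells, cfg.classify.n_components, cfg.classify.covariance_policy)
    log.info("segmented cross-validation (segment=%d)", cfg.classify.segment_size)
    seg_cm = segmented_cv(
        cells, cfg.classify.segment_size, cfg.classify.n_components,
        cfg.classify.covariance_policy,
    )
    return PipelineResult(
        cells_raw=cells_raw,
        backgrounds=backgrounds,
        cells=cells,
        band_table=table,
        grade_summary=summary,
        explained_variance_fraction=pca.explained_variance_fraction,
        scores=scores,
        loo_confusion=loo_cm,
        loo_report=report(loo_cm),
        seg_confusion=seg_cm,
        seg_report=report(seg_cm),
    )


def _confusion_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        cm.counts,
        index=[f"actual_{c}" for c in cm.labels],
        columns=[f"predicted_{c}" for c in cm.labels],
    )


def _config_echo(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return enc(cfg)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the analysis and write all artifacts under ``out_dir``."""
    cfg = config.resolved()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = run_analysis(cfg)

    write_set(res.cells_raw, out / "cohort" / "cells")
    write_set(res.backgrounds, out / "cohort" / "backgrounds")
    write_set(res.cells, out / "preprocessed")
    res.band_table.to_csv(out / "band_areas.tsv", sep="\t", index=False)
    res.grade_summary.to_csv(out / "grade_summary.tsv", sep="\t", index=False)

    means = grade_mean_spectra(res.cells)
    for g, s in means.items():
        write_spectrum(s, out / f"grade_mean_{g}.csv")
    write_spectrum(variance_spectrum(means), out / "variance_spectrum.csv")

    pca = pca_fit(res.cells, cfg.classify.n_components)
    pd.DataFrame(
        pca.loadings.T,
        columns=[f"PC{i + 1}" for i in range(pca.n_components)],
    ).assign(wavenumber_cm1=res.cells.grid.values).to_csv(
        out / "loadings.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        res.scores, columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])]
    ).assign(
        cell_id=res.cells.manifest["cell_id"], grade=res.cells.manifest["grade"]
    ).to_csv(out / "scores.tsv", sep="\t", index=False)

    _confusion_frame(res.loo_confusion).to_csv(out / "confusion_loo.tsv", sep="\t")
    _confusion_frame(res.seg_confusion).to_csv(out / "confusion_segmented.tsv", sep="\t")

    report_obj = {
        "seed": cfg.synth.seed,
        "n_spectra": len(res.cells),
        "explained_variance_fraction": res.explained_variance_fraction.tolist(),
        "loo": res.loo_report.to_dict(),
        "segmented": res.seg_report.to_dict(),
        "loo_confusion": res.loo_confusion.counts.tolist(),
        "segmented_confusion": res.seg_confusion.counts.tolist(),
    }
    (out / "report.json").write_text(json.dumps(report_obj, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(_config_echo(cfg), sort_keys=False))
    (out / "run_log.txt").write_text(
        "\n".join(
            [
                f"chondrospec {__version__}",
                f"python {platform.python_version()}",
                f"numpy {np.__version__}",
                f"seed {cfg.synth.seed}",
                f"n_cells {len(res.cells)}",
            ]
        )
        + "\n"
    )
    return out


def table1_demo() -> ClassificationReport:
    """Metrics for the packaged reference classification matrix.

    The matrix (450 spectra, 150 per grade) yields an overall predictive
    efficiency of 92.2% under one-decimal truncation; per-class
    column-wise predictive values are 98.6 / 82.8 / 97.5 and the negative
    predictive values for grades I and II are 100.0 / 98.1.  Note the
    grade-III negative predictive value computes to 90.8 (297/327).
    """
    return report(REFERENCE_CONFUSION)
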