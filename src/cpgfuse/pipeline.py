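"""End-to-end orchestration: data, CpG split, models, associations, reports.

The pipeline runs, in order: data synthesis or ingest; the CpG-content
split; per (HM, class) model training for the CpG-poor, CpG-rich and
all-genes sets (nested CV plus a final refit, each set normalized on its
own genes); association scoring; partial correlations per class; and a
rich-vs-poor performance comparison per HM (unpaired exact Wilcoxon
rank-sum on the outer-fold Pearson values, Benjamini-Hochberg across HMs).
Every numeric output is written as TSV/JSON with a config echo; rerunning
an identical config reproduces all artifacts byte-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import association as assoc
from . import io as cio
from . import partialcorr as pc
from .fused import FeatureChainGraph, nested_cv
from .promoters import POOR, RICH, SignalBundle, fit_bimodal_split
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

ALL = "all"
MODEL_SETS = (RICH, POOR, ALL)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (statistical constants are the
    study's defaults: alpha_assoc 0.005, alpha_pc 0.01 with 10000
    permutations, alpha_perf 0.05)."""

    seed: int
    outdir: str
    mode: str = "synthetic"  # synthetic | matrices
    synthetic: SyntheticConfig | None = None
    tf_path: str | None = None
    hm_path: str | None = None
    cpg_path: str | None = None
    up: int = 500
    down: int = 500
    bin_width: int = 100
    gamma_grid: tuple = (0.0, 1e-3, 1e-2, 0.1, 1.0, 10.0)
    outer_folds: int = 5
    inner_folds: int = 3
    n_lambda2: int = 10
    lambda2_decades: float = 4.0
    alpha_assoc: float = 0.005
    alpha_pc: float = 0.01
    n_perm: int = 10000
    alpha_perf: float = 0.05
    normalize_response: bool = True
    pseudocount: float = 1.0
    threads: int = 1

    def validate(self) -> None:
        for a in (self.alpha_assoc, self.alpha_pc, self.alpha_perf):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")
        if (self.up + self.down) % self.bin_width != 0:
            raise ValueError("window length must be divisible by bin width")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.mode not in ("synthetic", "matrices"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ModelResult:
    hm: str
    model_set: str  # rich | poor | all
    cv_report: object
    fit: object
    table: assoc.AssociationTable
    n_genes: int


@dataclass
class PerformanceComparison:
    hm: str
    rich_pearson: np.ndarray
    poor_pearson: np.ndarray
    all_pearson: np.ndarray
    statistic: float
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False


@dataclass
class PipelineResult:
    config: RunConfig
    partition: object
    models: dict = field(default_factory=dict)   # (hm, set) -> ModelResult
    pcor: dict = field(default_factory=dict)     # class -> PartialCorrelationResult
    performance: list = field(default_factory=list)


def compare_performance(fold_rich: np.ndarray, fold_poor: np.ndarray,
                        hm: str = "", fold_all: np.ndarray | None = None
                        ) -> PerformanceComparison:
    """Unpaired exact Wilcoxon rank-sum on outer-fold Pearson values.

    Fold test sets contain different genes in the two classes, so pairing
    is undefined and the two-sample rank-sum test applies.
    """
    r = np.asarray(fold_rich, dtype=float)
    p = np.asarray(fold_poor, dtype=float)
    if len(r) < 3 or len(p) < 3:
        raise ValueError("need at least 3 folds per class")
    res = sps.mannwhitneyu(r, p, alternative="two-sided", method="exact")
    return PerformanceComparison(hm=hm, rich_pearson=r, poor_pearson=p,
                                 all_pearson=(np.asarray(fold_all, dtype=float)
                                              if fold_all is not None
                                              else np.array([])),
                                 statistic=float(res.statistic),
                                 p_raw=float(res.pvalue))


def bh_adjust(comparisons: list[PerformanceComparison],
              alpha: float = 0.05) -> None:
    """Benjamini-Hochberg across the HMs of one run, in place."""
    if not comparisons:
        return
    raw = [c.p_raw for c in comparisons]
    reject, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    for c, a, rej in zip(comparisons, adj, reject):
        c.p_adj = float(a)
        c.significant = bool(rej)


def _prepare_bundle(config: RunConfig):
    """Stage 1: synthesize or load the raw signal bundle + CpG counts."""
    if config.mode == "synthetic":
        if config.synthetic is None:
            raise ValueError("synthetic mode requires a SyntheticConfig")
        ds = generate_dataset(config.synthetic)
        bundle = SignalBundle(genes=ds.gene_ids, tf_names=ds.tf_names,
                              hm_names=ds.hm_names,
                              bin_count=ds.config.n_bins,
                              X_raw=ds.tf_raw, y_raw=ds.hm_raw)
        return bundle, ds.cpg_counts, ds
    bundle = cio.load_signal_bundle(config.tf_path, config.hm_path)
    cpg = pd.read_csv(config.cpg_path, sep="\t")
    cpg = cpg.set_index("gene_id").loc[bundle.genes, "cpg_count"].to_numpy()
    return bundle, cpg, None


def _model_rows(labels: np.ndarray, model_set: str) -> np.ndarray:
    if model_set == ALL:
        return np.arange(len(labels))
    return np.nonzero(labels == model_set)[0]


def _fit_one_model(bundle: SignalBundle, rows: np.ndarray, hm_idx: int,
                   config: RunConfig, model_seed: int,
                   model_set: str) -> ModelResult:
    sub = bundle.subset(rows).normalize(config.pseudocount,
                                        config.normalize_response)
    graph = FeatureChainGraph(len(bundle.tf_names), bundle.bin_count)
    y = sub.y_norm[:, hm_idx]
    report, fit = nested_cv(sub.X_norm, y, graph,
                            gamma_grid=config.gamma_grid,
                            outer_folds=config.outer_folds,
                            inner_folds=config.inner_folds,
                            n_lambda2=config.n_lambda2,
                            lambda2_decades=config.lambda2_decades,
                            seed=model_seed)
    records = assoc.score_all_tfs(fit, sub.X_norm, y, graph,
                                  tf_names=bundle.tf_names)
    table = assoc.rank_associations(
        records, alpha=config.alpha_assoc,
        model_id=f"{bundle.hm_names[hm_idx]}:{model_set}")
    return ModelResult(hm=bundle.hm_names[hm_idx], model_set=model_set,
                       cv_report=report, fit=fit, table=table,
                       n_genes=len(rows))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write artifacts under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    t0 = time.time()
    try:
        bundle, cpg_counts, ds = _prepare_bundle(config)
    except Exception as exc:
        raise RuntimeError(f"stage ingest failed: {exc}") from exc
    log("ingest", f"{len(bundle.genes)} genes, {len(bundle.tf_names)} TFs, "
        f"{len(bundle.hm_names)} HMs")
    if ds is not None:
        cio.write_dataset(ds, outdir / "dataset")

    try:
        partition = fit_bimodal_split(cpg_counts, seed=config.seed)
    except Exception as exc:
        raise RuntimeError(f"stage cpg_split failed: {exc}") from exc
    log("cpg_split", f"threshold {partition.threshold:.3f}: "
        f"{partition.n_poor} poor / {partition.n_rich} rich")
    pd.DataFrame({"gene_id": bundle.genes, "cpg_count": partition.counts,
                  "cpg_class": partition.labels}).to_csv(
        outdir / "cpg_partition.tsv", sep="\t", index=False)

    # per (HM, set) models; seeds derived deterministically from the run seed
    jobs = []
    for h, hm in enumerate(bundle.hm_names):
        for s, model_set in enumerate(MODEL_SETS):
            model_seed = (config.seed * 1000003 + h * 101 + s) % (2 ** 31 - 1)
            rows = _model_rows(partition.labels, model_set)
            jobs.append((h, model_set, rows, model_seed))

    def run_job(job):
        h, model_set, rows, model_seed = job
        return _fit_one_model(bundle, rows, h, config, model_seed, model_set)

    try:
        if config.threads > 1:
            from joblib import Parallel, delayed
            results = Parallel(n_jobs=config.threads)(
                delayed(run_job)(j) for j in jobs)
        else:
            results = [run_job(j) for j in jobs]
    except Exception as exc:
        raise RuntimeError(f"stage models failed: {exc}") from exc

    result = PipelineResult(config=config, partition=partition)
    tables = {}
    for mr in results:
        result.models[(mr.hm, mr.model_set)] = mr
        tables[mr.table.model_id] = mr.table
        sel = mr.cv_report.folds[0]
        log("models", f"{mr.hm}/{mr.model_set}: n={mr.n_genes}, "
            f"fold0 gamma={sel.gamma:g} lambda2={sel.lambda2:.4g}, "
            f"mean Pearson={np.mean(mr.cv_report.pearson):.4f}")
        stem = outdir / f"model_{mr.hm}_{mr.model_set}"
        mr.table.to_frame().to_csv(f"{stem}_associations.tsv", sep="\t",
                                   index=False, float_format=cio.FLOAT_FMT)
        mr.cv_report.to_frame().to_csv(f"{stem}_cv.tsv", sep="\t",
                                       index=False, float_format=cio.FLOAT_FMT)
        Path(f"{stem}_fit.json").write_text(cio.fit_to_json(mr.fit))
    sign = assoc.presence_sign_matrix(tables, bundle.tf_names)
    sign.to_csv(outdir / "association_sign_matrix.tsv", sep="\t",
                index_label="tf")

    # partial correlations per class on the same normalization as responses
    if len(bundle.hm_names) >= 3:
        try:
            long_frames = []
            for cls in (RICH, POOR):
                rows = _model_rows(partition.labels, cls)
                sub = bundle.subset(rows).normalize(config.pseudocount,
                                                    config.normalize_response)
                res = pc.pc_matrix(sub.y_norm, bundle.hm_names,
                                   class_label=cls, alpha=config.alpha_pc,
                                   n_perm=config.n_perm,
                                   seed=(config.seed * 7919
                                         + {RICH: 1, POOR: 2}[cls])
                                   % (2 ** 31 - 1))
                result.pcor[cls] = res
                long_frames.append(res.to_long_frame())
                pd.DataFrame(res.rho, index=bundle.hm_names,
                             columns=bundle.hm_names).to_csv(
                    outdir / f"pcor_rho_{cls}.tsv", sep="\t",
                    float_format=cio.FLOAT_FMT)
            pd.concat(long_frames).to_csv(outdir / "pcor_long.tsv", sep="\t",
                                          index=False,
                                          float_format=cio.FLOAT_FMT)
            log("pcor", f"{result.pcor[RICH].n_pairs} pairs per class tested")
        except Exception as exc:
            raise RuntimeError(f"stage pcor failed: {exc}") from exc
    else:
        log("pcor", "skipped: fewer than 3 HMs")

    # rich vs poor performance per HM
    try:
        comps = []
        for hm in bundle.hm_names:
            comp = compare_performance(
                result.models[(hm, RICH)].cv_report.pearson,
                result.models[(hm, POOR)].cv_report.pearson, hm=hm,
                fold_all=result.models[(hm, ALL)].cv_report.pearson)
            comps.append(comp)
        bh_adjust(comps, alpha=config.alpha_perf)
        result.performance = comps
    except Exception as exc:
        raise RuntimeError(f"stage performance failed: {exc}") from exc
    perf = pd.DataFrame([dict(
        hm=c.hm, mean_rich=c.rich_pearson.mean(), mean_poor=c.poor_pearson.mean(),
        mean_all=(c.all_pearson.mean() if len(c.all_pearson) else np.nan),
        W=c.statistic, p_raw=c.p_raw, p_bh=c.p_adj, significant=c.significant)
        for c in comps])
    perf.to_csv(outdir / "performance_comparison.tsv", sep="\t", index=False,
                float_format=cio.FLOAT_FMT)
    log("performance", f"{int(perf.significant.sum())} of {len(perf)} HMs "
        f"differ at BH alpha={config.alpha_perf}")

    echo = dataclasses.asdict(config)
    echo["synthetic"] = (None if config.synthetic is None else
                         json.loads((outdir / "dataset" /
                                     "synthetic_config.json").read_text())
                         if config.mode == "synthetic" else None)
    (outdir / "run_config.json").write_text(
        json.dumps(echo, indent=2, sort_keys=True, default=str))
    log("done", f"total wall {time.time() - t0:.1f}s")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return result
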