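"""Canonical synthetic study designs and recovery experiments.

These functions define the planted-truth benchmark conditions used to
validate the analysis end-to-end: a 50-TF, 10-bin design with five
planted TFs per CpG class (block-constant coefficients, one sign change
between classes, one class-exclusive TF per class) at noise targeting a
within-class R^2 of 0.8, plus null, noiseless-ceiling, and
partial-correlation sign-flip designs.  The experiments are run both by
the test suite and by the acceptance script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import association as assoc
from .fused import FeatureChainGraph, _grid_select, fit_fused_lasso, \
    lambda2_grid, lambda2_max, nested_cv
from .promoters import POOR, RICH, SignalBundle, fit_bimodal_split
from .synthetic import (SyntheticConfig, block_coefficients,
                        generate_dataset, noise_sd_for_r2)

#: planted design: tf_index -> (bin range, value) per class; TF1 flips sign
#: between classes, TF4 is poor-exclusive and TF5 rich-exclusive.
RECOVERY_PLAN = {
    POOR: {0: (0, 10, 2.0), 1: (0, 5, -1.5), 2: (2, 8, 1.8),
           3: (5, 10, 1.2), 4: (0, 10, -2.0)},
    RICH: {0: (0, 10, 2.0), 1: (0, 5, 1.5), 2: (2, 8, 1.8),
           3: (5, 10, 1.2), 5: (0, 10, 2.0)},
}


def recovery_config(seed: int, n_genes: int = 2000, n_tfs: int = 50,
                    n_bins: int = 10, r2: float = 0.8) -> SyntheticConfig:
    """Benchmark dataset config with the standard planted association sets.

    The noise standard deviation is calibrated per seed so the planted
    signal explains a within-class variance fraction of ``r2``.
    """
    planted = {cls: [{tf: block_coefficients(n_bins, a, b, v)
                      for tf, (a, b, v) in RECOVERY_PLAN[cls].items()}]
               for cls in (POOR, RICH)}
    cfg = SyntheticConfig(n_genes=n_genes, n_tfs=n_tfs, n_bins=n_bins,
                          planted=planted, noise_sd=0.0, seed=seed)
    return dataclasses.replace(cfg, noise_sd=noise_sd_for_r2(cfg, r2))


def _class_bundle(ds, labels, cls) -> SignalBundle:
    rows = np.nonzero(labels == cls)[0]
    bundle = SignalBundle(genes=[ds.gene_ids[i] for i in rows],
                          tf_names=ds.tf_names, hm_names=ds.hm_names,
                          bin_count=ds.config.n_bins,
                          X_raw=ds.tf_raw[rows], y_raw=ds.hm_raw[rows])
    # the planted model lives on the response scale: features normalized,
    # response raw
    return bundle.normalize(normalize_response=False)


def select_penalties(seed: int = 0, gamma_grid=(0.01, 0.1, 1.0),
                     n_lambda2: int = 8, decades: float = 3.0,
                     inner_folds: int = 3, **config_kw) -> dict:
    """Choose (lambda1, lambda2) per CpG class by K-fold CV on an
    independent tuning replicate of the benchmark design."""
    cfg = recovery_config(seed, **config_kw)
    ds = generate_dataset(cfg)
    labels = fit_bimodal_split(ds.cpg_counts, seed=seed).labels
    graph = FeatureChainGraph(cfg.n_tfs, cfg.n_bins)
    out = {}
    rng = np.random.default_rng(seed)
    for cls in (POOR, RICH):
        sub = _class_bundle(ds, labels, cls)
        y = sub.y_norm[:, 0]
        l2max = lambda2_max(sub.X_norm, y, graph, max_iter=2000)
        lam2s = lambda2_grid(l2max, n_lambda2, decades)
        gamma, lam2 = _grid_select(sub.X_norm, y, graph, gamma_grid, lam2s,
                                   inner_folds, rng,
                                   dict(tol=1e-7, max_iter=2000))
        out[cls] = (gamma * lam2, lam2)
    return out


@dataclass
class RecoveryRun:
    seed: int
    top: dict       # class -> list of (tf_name, sign)
    planted_found: dict  # class -> bool (all planted in top-10, right sign)
    exclusive_ok: dict   # class -> bool (own exclusive in, other's out)


def run_recovery(seed: int, penalties: dict, alpha: float = 0.005,
                 **config_kw) -> RecoveryRun:
    """One benchmark replicate: generate, split, fit per class, rank TFs."""
    cfg = recovery_config(seed, **config_kw)
    ds = generate_dataset(cfg)
    labels = fit_bimodal_split(ds.cpg_counts, seed=seed).labels
    graph = FeatureChainGraph(cfg.n_tfs, cfg.n_bins)
    top, found, excl = {}, {}, {}
    exclusive = {POOR: "TF004", RICH: "TF005"}
    for cls in (POOR, RICH):
        sub = _class_bundle(ds, labels, cls)
        y = sub.y_norm[:, 0]
        l1, l2 = penalties[cls]
        fit = fit_fused_lasso(sub.X_norm, y, graph, l1, l2, tol=1e-8,
                              max_iter=5000)
        records = assoc.score_all_tfs(fit, sub.X_norm, y, graph,
                                      tf_names=ds.tf_names)
        table = assoc.rank_associations(records, alpha=alpha, top=10,
                                        model_id=f"HM0:{cls}")
        top[cls] = [(r.tf_name, r.sign) for r in table.significant_top]
    for cls in (POOR, RICH):
        got = dict(top[cls])
        want = {f"TF{tf:03d}": ("positive" if v > 0 else "negative")
                for tf, (_, _, v) in RECOVERY_PLAN[cls].items()}
        found[cls] = all(got.get(name) == sign for name, sign in want.items())
        other = RICH if cls == POOR else POOR
        # this class's exclusive TF detected in its home class only
        excl[cls] = (exclusive[cls] in dict(top[cls])
                     and exclusive[cls] not in dict(top[other]))
    return RecoveryRun(seed=seed, top=top, planted_found=found,
                       exclusive_ok=excl)


def recovery_experiment(n_seeds: int = 20, base_seed: int = 1000,
                        penalties: dict | None = None, **config_kw) -> dict:
    """Recovery rates over ``n_seeds`` benchmark replicates.

    Returns rates in [0, 1] for: all planted TFs in the top-10 with the
    correct sign (per class and jointly), and each class-exclusive planted
    TF detected only in its own class (averaged over the two such TFs).
    """
    if penalties is None:
        penalties = select_penalties(seed=base_seed - 1, **config_kw)
    runs = [run_recovery(base_seed + i, penalties, **config_kw)
            for i in range(n_seeds)]
    excl_poor = np.mean([r.exclusive_ok[POOR] for r in runs])
    excl_rich = np.mean([r.exclusive_ok[RICH] for r in runs])
    return {
        "planted_rate_poor": np.mean([r.planted_found[POOR] for r in runs]),
        "planted_rate_rich": np.mean([r.planted_found[RICH] for r in runs]),
        "planted_rate_both": np.mean([r.planted_found[POOR]
                                      and r.planted_found[RICH]
                                      for r in runs]),
        "exclusive_rate_poor_tf": excl_poor,
        "exclusive_rate_rich_tf": excl_rich,
        "exclusive_rate": 0.5 * (excl_poor + excl_rich),
        "runs": runs,
        "penalties": penalties,
    }


def null_cv_experiment(n_seeds: int = 10, n_genes: int = 150, n_tfs: int = 5,
                       n_bins: int = 4, base_seed: int = 7000) -> float:
    """Mean outer-fold Pearson of nested CV on shuffled (null) responses."""
    graph = FeatureChainGraph(n_tfs, n_bins)
    vals = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        X = rng.uniform(0, 1, (n_genes, n_tfs * n_bins))
        beta = rng.normal(0, 1, n_tfs * n_bins)
        y = X @ beta + rng.normal(0, 0.5, n_genes)
        y = rng.permutation(y)  # break the gene alignment
        rep, _ = nested_cv(X, y, graph, gamma_grid=(0.0, 0.1, 1.0),
                           n_lambda2=4, lambda2_decades=3.0,
                           seed=base_seed + i, tol=1e-7, max_iter=2000)
        vals.extend(rep.pearson)
    return float(np.mean(vals))


def noiseless_ceiling_experiment(seed: int = 4000, n_genes: int = 400,
                                 n_tfs: int = 8, n_bins: int = 6) -> np.ndarray:
    """Outer-fold Pearson values of class models on noiseless planted data."""
    planted = {cls: [{0: block_coefficients(n_bins, 0, n_bins, 2.0),
                      1: block_coefficients(n_bins, 0, n_bins // 2, -1.5)}]
               for cls in (POOR, RICH)}
    cfg = SyntheticConfig(n_genes=n_genes, n_tfs=n_tfs, n_bins=n_bins,
                          planted=planted, noise_sd=0.0, seed=seed)
    ds = generate_dataset(cfg)
    labels = fit_bimodal_split(ds.cpg_counts, seed=seed).labels
    graph = FeatureChainGraph(n_tfs, n_bins)
    vals = []
    for cls in (POOR, RICH):
        sub = _class_bundle(ds, labels, cls)
        rep, _ = nested_cv(sub.X_norm, sub.y_norm[:, 0], graph,
                           gamma_grid=(0.0, 0.01, 0.1), n_lambda2=5,
                           lambda2_decades=4.0, seed=seed, tol=1e-9,
                           max_iter=10000)
        vals.extend(rep.pearson)
    return np.asarray(vals)


def sign_flip_experiment(n_seeds: int = 20, n_per_class: int = 300,
                         base_seed: int = 5000) -> float:
    """Rate of recovering a planted cross-class sign flip in the partial
    correlation of an HM pair (coupling +0.8 in rich, -0.8 in poor, one
    shared confounder conditioned away)."""
    from .partialcorr import pc_matrix

    hits = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        ok = True
        for cls_sign in (+1.0, -1.0):
            latent = rng.normal(size=n_per_class)
            conf = rng.normal(size=n_per_class)
            Y = np.column_stack([
                latent + 0.7 * conf + 0.4 * rng.normal(size=n_per_class),
                cls_sign * 0.8 * latent + 0.7 * conf
                + 0.4 * rng.normal(size=n_per_class),
                conf + 0.4 * rng.normal(size=n_per_class)])
            res = pc_matrix(Y, ["HMa", "HMb", "HMconf"], n_perm=99,
                            seed=base_seed + i)
            ok &= (res.rho[0, 1] > 0) == (cls_sign > 0)
        hits += ok
    return hits / n_seeds
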