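"""Tab-separated matrix dialect and result serialization.

All matrices are UTF-8 TSV with the gene id in the first column.  TF
feature files carry one column per (TF, bin) named ``tf_name:bin`` with
1-based bin indices in gene orientation; HM response files carry one
column per HM.  Floats are written with 12 significant digits so reruns
with identical configs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.12g"


def _check_genes(gene_ids) -> list[str]:
    genes = [str(g) for g in gene_ids]
    dupes = pd.Index(genes)[pd.Index(genes).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate gene id {dupes[0]!r}")
    return genes


def tf_columns(tf_names: list[str], k: int) -> list[str]:
    return [f"{tf}:{b}" for tf in tf_names for b in range(1, k + 1)]


def write_matrix_tsv(path, gene_ids, matrix: np.ndarray,
                     columns: list[str]) -> None:
    genes = _check_genes(gene_ids)
    matrix = np.asarray(matrix)
    if matrix.shape != (len(genes), len(columns)):
        raise ValueError(f"matrix shape {matrix.shape} does not match "
                         f"{len(genes)} genes x {len(columns)} columns")
    df = pd.DataFrame(matrix, columns=columns)
    df.insert(0, "gene_id", genes)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_matrix_tsv(path) -> tuple[list[str], np.ndarray, list[str]]:
    """Returns (gene_ids, matrix, column names); validates the dialect."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be gene_id, "
                         f"got {df.columns[0]!r}")
    genes = _check_genes(df["gene_id"])
    data = df.drop(columns="gene_id")
    bad = [c for c in data.columns
           if not np.issubdtype(data[c].dtype, np.number)]
    if bad:
        rows = data[bad[0]].map(
            lambda v: not isinstance(v, (int, float))).idxmax()
        raise ValueError(f"{path}: non-numeric cell in column {bad[0]!r} "
                         f"near row {rows + 2}")
    if data.isna().any().any():
        r, c = np.argwhere(data.isna().values)[0]
        raise ValueError(f"{path}: missing/ragged value at row {r + 2}, "
                         f"column {data.columns[c]!r}")
    return genes, data.to_numpy(dtype=float), list(data.columns)


def parse_tf_columns(columns: list[str]) -> tuple[list[str], int]:
    """Recover (tf_names, k) from ``tf:bin`` headers; validates layout."""
    names: list[str] = []
    ks: dict[str, list[int]] = {}
    for col in columns:
        if ":" not in col:
            raise ValueError(f"TF column {col!r} is not in tf_name:bin form")
        tf, b = col.rsplit(":", 1)
        if tf not in ks:
            ks[tf] = []
            names.append(tf)
        ks[tf].append(int(b))
    k_set = {tuple(v) for v in ks.values()}
    if len(k_set) != 1:
        raise ValueError("inconsistent bin counts across TFs")
    bins = k_set.pop()
    if list(bins) != list(range(1, len(bins) + 1)):
        raise ValueError("bins must be 1..k in order within each TF")
    return names, len(bins)


def load_signal_bundle(tf_path, hm_path):
    """Read aligned TF-feature and HM-response TSVs into a SignalBundle."""
    from .promoters import SignalBundle

    genes_x, X, cols_x = read_matrix_tsv(tf_path)
    genes_y, Y, cols_y = read_matrix_tsv(hm_path)
    if genes_x != genes_y:
        raise ValueError("gene order mismatch between TF and HM files")
    tf_names, k = parse_tf_columns(cols_x)
    return SignalBundle(genes=genes_x, tf_names=tf_names, hm_names=cols_y,
                        bin_count=k, X_raw=X, y_raw=Y)


def write_dataset(dataset, outdir) -> dict[str, Path]:
    """Write a SyntheticDataset as the standard TSVs plus truth sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    paths = {
        "tf": outdir / "tf_signals.tsv",
        "hm": outdir / "hm_signals.tsv",
        "cpg": outdir / "cpg_counts.tsv",
        "truth": outdir / "truth_coefficients.tsv",
        "config": outdir / "synthetic_config.json",
    }
    write_matrix_tsv(paths["tf"], dataset.gene_ids, dataset.tf_raw,
                     tf_columns(dataset.tf_names, cfg.n_bins))
    write_matrix_tsv(paths["hm"], dataset.gene_ids, dataset.hm_raw,
                     dataset.hm_names)
    cpg = pd.DataFrame({"gene_id": dataset.gene_ids,
                        "cpg_count": dataset.cpg_counts,
                        "true_class": dataset.truth.labels})
    cpg.to_csv(paths["cpg"], sep="\t", index=False)
    rows = []
    for cls, per_hms in dataset.truth.planted.items():
        for h, mapping in enumerate(per_hms):
            for tf, coefs in mapping.items():
                for b, c in enumerate(np.atleast_1d(coefs), start=1):
                    rows.append(dict(hm=dataset.hm_names[h], cls=cls,
                                     tf_index=tf, bin=b, coefficient=c))
    pd.DataFrame(rows, columns=["hm", "cls", "tf_index", "bin",
                                "coefficient"]).to_csv(
        paths["truth"], sep="\t", index=False, float_format=FLOAT_FMT)
    echo = dict(n_genes=cfg.n_genes, n_tfs=cfg.n_tfs, n_bins=cfg.n_bins,
                noise_sd=cfg.noise_sd, background=list(cfg.background),
                seed=cfg.seed,
                cpg_mixture=[[c.weight, c.mean, c.sd] for c in cfg.cpg_mixture],
                true_threshold=dataset.truth.threshold)
    paths["config"].write_text(json.dumps(echo, indent=2, sort_keys=True))
    return paths


def fit_to_json(fit) -> str:
    return json.dumps(dict(
        beta0=fit.beta0, beta=list(fit.beta), lambda1=fit.lambda1,
        lambda2=fit.lambda2, gamma=fit.gamma, rss=fit.rss, df=fit.df,
        converged=fit.converged, n_iter=fit.n_iter,
        blocks=[[list(b) for b in chain] for chain in fit.blocks]),
        indent=2)
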