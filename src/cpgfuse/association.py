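"""TF-HM association scoring by the approximate-refit F-test.

Each TF's contribution to a fitted fused model is scored by zeroing its k
bin coefficients (without refitting) and comparing the resulting reduced-
model RSS against the full-model RSS with a nested-model F-statistic

    F = ((RSS0 - RSS_full) / (df_full - df_0))
        * ((N - df_full - 1) / RSS_full)

where degrees of freedom count nonzero fused coefficient blocks.  The
reported associations per model are the TFs with the ten lowest p-values
below the significance cutoff (default alpha = 0.005), each carrying the
sign of its summed bin coefficients.  No multiple-testing correction is
applied across TFs; the fixed alpha plus top-10 rule is the selection
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fused import FeatureChainGraph, FusedFitResult, count_df


@dataclass
class AssociationRecord:
    tf_name: str
    tf_index: int
    coef_sum: float
    sign: str  # "positive" | "negative" | "zero"
    rss0: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    tested: bool = True


@dataclass
class AssociationTable:
    """All per-TF records for one (HM, CpG class) model plus the top-10 cut."""

    model_id: str
    records: list[AssociationRecord]
    significant_top: list[AssociationRecord] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        ranked = {id(r): i + 1 for i, r in enumerate(self.significant_top)}
        df = pd.DataFrame([dict(tf=r.tf_name, coef_sum=r.coef_sum, sign=r.sign,
                                F=r.f_stat, df_num=r.df_num, df_den=r.df_den,
                                p=r.p_value, rank=ranked.get(id(r), 0))
                           for r in self.records])
        return df.sort_values(["p", "tf"]).reset_index(drop=True)


def f_statistic(rss0: float, rss_full: float, df0: int, df_full: int,
                n: int) -> tuple[float, int, int]:
    """Nested-model F with fused block degrees of freedom.

    Returns (F, df_num, df_den) with df_num = df_full - df0 and
    df_den = n - df_full - 1.
    """
    df_num = df_full - df0
    df_den = n - df_full - 1
    if df_num <= 0 or df_den <= 0 or rss_full <= 0:
        return 0.0, max(df_num, 0), df_den
    f = (rss0 - rss_full) / df_num * (df_den / rss_full)
    return max(0.0, f), df_num, df_den


def _sign_label(coef_sum: float, tol: float) -> str:
    if coef_sum > tol:
        return "positive"
    if coef_sum < -tol:
        return "negative"
    return "zero"


def f_test_tf(fit: FusedFitResult, X: np.ndarray, y: np.ndarray,
              tf_index: int, graph: FeatureChainGraph,
              tf_name: str | None = None) -> AssociationRecord:
    """Score one TF by the zero-out nested-model F-test.

    RSS0 comes from predictions with the TF's k coefficients set to zero
    (no refit); df of either model counts nonzero fused blocks.  A TF whose
    coefficients are already all zero is untestable: F=0, p=1, flagged.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; associations would be unreliable")
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    sl = graph.tf_slice(tf_index)
    name = tf_name if tf_name is not None else f"TF{tf_index:03d}"

    tol = 1e-6 * max(1e-30, float(np.max(np.abs(fit.beta))))
    coef_sum = float(fit.beta[sl].sum())

    beta0_vec = fit.beta.copy()
    beta0_vec[sl] = 0.0
    resid0 = y - fit.beta0 - X @ beta0_vec
    rss0 = float(resid0 @ resid0)

    df_full = count_df(fit.beta, graph, tol=tol)
    df_reduced = count_df(beta0_vec, graph, tol=tol)
    f_stat, df_num, df_den = f_statistic(rss0, fit.rss, df_reduced, df_full, n)
    if df_den <= 0:
        raise ValueError(f"nonpositive denominator df (N={n}, df_full={df_full})")
    if df_num <= 0:
        return AssociationRecord(tf_name=name, tf_index=tf_index,
                                 coef_sum=coef_sum,
                                 sign=_sign_label(coef_sum, tol), rss0=rss0,
                                 f_stat=0.0, df_num=0, df_den=df_den,
                                 p_value=1.0, tested=False)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return AssociationRecord(tf_name=name, tf_index=tf_index, coef_sum=coef_sum,
                             sign=_sign_label(coef_sum, tol), rss0=rss0,
                             f_stat=f_stat, df_num=df_num, df_den=df_den,
                             p_value=p)


def score_all_tfs(fit: FusedFitResult, X: np.ndarray, y: np.ndarray,
                  graph: FeatureChainGraph,
                  tf_names: list[str] | None = None) -> list[AssociationRecord]:
    names = tf_names if tf_names is not None else [f"TF{i:03d}"
                                                   for i in range(graph.m)]
    return [f_test_tf(fit, X, y, i, graph, tf_name=names[i])
            for i in range(graph.m)]


def rank_associations(records: list[AssociationRecord], *, alpha: float = 0.005,
                      top: int = 10, model_id: str = "") -> AssociationTable:
    """Filter p < alpha, sort ascending by p, keep at most ``top`` records.

    Ties in p are broken by larger |coef_sum|, then by TF name.
    """
    sig = [r for r in records if r.p_value < alpha]
    sig.sort(key=lambda r: (r.p_value, -abs(r.coef_sum), r.tf_name))
    return AssociationTable(model_id=model_id, records=list(records),
                            significant_top=sig[:top])


def coefficient_profile(fit: FusedFitResult, tf_index: int,
                        graph: FeatureChainGraph
                        ) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Per-bin coefficients of one TF in gene orientation, with block runs.

    Returns (k-vector, blocks) where blocks are (start_bin,
    end_bin_exclusive, value) triples — the heatmap-ready profile.
    """
    sl = graph.tf_slice(tf_index)
    coefs = fit.beta[sl].copy()
    blocks = fit.blocks[tf_index] if fit.blocks else []
    return coefs, blocks


def presence_sign_matrix(tables: dict[str, AssociationTable],
                         tf_names: list[str]):
    """Across-model presence/sign matrix: rows TFs, columns model ids,
    entries '+', '-' or '.' (absent from the significant top list)."""
    import pandas as pd
    cols = {}
    for model_id, table in tables.items():
        col = {name: "." for name in tf_names}
        for rec in table.significant_top:
            col[rec.tf_name] = "+" if rec.sign == "positive" else (
                "-" if rec.sign == "negative" else ".")
        cols[model_id] = col
    return pd.DataFrame(cols).loc[tf_names]
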