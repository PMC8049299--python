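"""Pairwise partial correlations between histone marks with permutation tests.

For each unordered pair of HMs (X, Y), the partial correlation given the
remaining marks Z is the Pearson correlation of the residuals of the two
OLS regressions X ~ Z and Y ~ Z (both with intercept).  Significance is
assessed by permuting one residual vector (n = 10000 permutations by
default) and, by default, comparing |rho| two-sidedly with an add-one
correction:

    p = (1 + #{ |rho_perm| >= |rho_obs| }) / (n_perm + 1)

The literal one-sided, divide-by-n estimator is available via flags.
Pairs are Bonferroni-corrected within each CpG class (factor C(n_hm, 2))
and called significant at alpha = 0.01.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def residualize(target: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``target`` on ``Z`` plus an intercept.

    With empty Z this is plain centering.  Rank-deficient Z is handled by
    least squares on the full design (dependent columns carry no extra
    information); a warning is logged.
    """
    t = np.asarray(target, dtype=float).ravel()
    if Z is None or (hasattr(Z, "size") and Z.size == 0):
        return t - t.mean()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != t.size:
        Z = Z.T
    if Z.shape[0] != t.size:
        raise ValueError("target and Z row counts differ")
    design = np.column_stack([np.ones(t.size), Z])
    coef, _, rank, _ = np.linalg.lstsq(design, t, rcond=None)
    if rank < design.shape[1]:
        logger.warning("rank-deficient conditioning set (rank %d of %d); "
                       "dependent columns contribute nothing", rank,
                       design.shape[1])
    return t - design @ coef


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        Z: np.ndarray | None) -> float:
    """Pearson correlation of the residuals of x ~ Z and y ~ Z."""
    rx = residualize(x, Z)
    ry = residualize(y, Z)
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # relative floor: residuals at rounding-error scale mean the target is
    # an exact linear function of Z
    x_ss = float(np.sum((np.asarray(x, float) - np.mean(x)) ** 2))
    y_ss = float(np.sum((np.asarray(y, float) - np.mean(y)) ** 2))
    if sx <= 1e-20 * max(1.0, x_ss) or sy <= 1e-20 * max(1.0, y_ss):
        raise ValueError("zero residual variance: degenerate conditioning")
    return float((rx @ ry) / np.sqrt(sx * sy))


def permutation_pvalue(rx: np.ndarray, ry: np.ndarray, *, n_perm: int = 10000,
                       seed: int = 0, two_sided: bool = True,
                       add_one: bool = True) -> float:
    """Permutation p-value for the correlation of two residual vectors.

    ``rx`` is permuted ``n_perm`` times with ``ry`` fixed.  The default is
    a two-sided test on |rho| with the add-one correction; ``two_sided=
    False`` with ``add_one=False`` gives the literal one-sided
    count-over-n estimator.
    """
    rx = np.asarray(rx, dtype=float).ravel()
    ry = np.asarray(ry, dtype=float).ravel()
    if rx.size != ry.size:
        raise ValueError("residual vectors differ in length")
    if rx.size < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom <= 0:
        raise ValueError("zero variance in residuals")
    obs = float(rxc @ ryc) / denom
    # permute rows of a (n_perm, n) tile of rxc; correlation is then a matvec
    perms = rng.permuted(np.tile(rxc, (n_perm, 1)), axis=1)
    stats_perm = perms @ ryc / denom
    if two_sided:
        exceed = int(np.sum(np.abs(stats_perm) >= abs(obs) - 1e-15))
    else:
        exceed = int(np.sum(stats_perm >= obs - 1e-15))
    if add_one:
        return (1 + exceed) / (n_perm + 1)
    return exceed / n_perm


@dataclass
class PartialCorrelationResult:
    """Partial-correlation matrix of one CpG class with permutation tests."""

    hm_names: list[str]
    class_label: str
    rho: np.ndarray         # symmetric, unit diagonal
    p_raw: np.ndarray       # permutation p per pair (diagonal NaN)
    p_bonf: np.ndarray
    significant: np.ndarray  # boolean mask at alpha on p_bonf
    n_perm: int
    seed: int
    alpha: float

    @property
    def n_pairs(self) -> int:
        h = len(self.hm_names)
        return h * (h - 1) // 2

    def to_long_frame(self):
        import pandas as pd
        rows = []
        for i, j in itertools.combinations(range(len(self.hm_names)), 2):
            rows.append(dict(cls=self.class_label, hm1=self.hm_names[i],
                             hm2=self.hm_names[j], rho=self.rho[i, j],
                             p_raw=self.p_raw[i, j], p_bonf=self.p_bonf[i, j],
                             significant=bool(self.significant[i, j])))
        return pd.DataFrame(rows)


def pc_matrix(hm_signals: np.ndarray, hm_names: list[str], *,
              class_label: str = "all", alpha: float = 0.01,
              n_perm: int = 10000, seed: int = 0, two_sided: bool = True,
              add_one: bool = True) -> PartialCorrelationResult:
    """All pairwise partial correlations of one gene class.

    For each unordered pair the conditioning set Z is every remaining HM.
    Bonferroni correction is over the C(n_hm, 2) pairs of this class.
    """
    Y = np.asarray(hm_signals, dtype=float)
    n, h = Y.shape
    if h != len(hm_names):
        raise ValueError("hm_names length does not match matrix")
    if h < 3:
        raise ValueError("need at least 3 HMs for nontrivial conditioning")
    if n < h + 2:
        raise ValueError(f"class has {n} genes; need at least {h + 2} "
                         "for the conditioning regressions")
    n_pairs = h * (h - 1) // 2
    rho = np.eye(h)
    p_raw = np.full((h, h), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(h), 2):
        others = [c for c in range(h) if c not in (i, j)]
        Z = Y[:, others]
        rx = residualize(Y[:, i], Z)
        ry = residualize(Y[:, j], Z)
        sx, sy = float(rx @ rx), float(ry @ ry)
        if sx <= 0 or sy <= 0:
            raise ValueError(f"zero residual variance for pair "
                             f"({hm_names[i]}, {hm_names[j]})")
        r = float((rx @ ry) / np.sqrt(sx * sy))
        p = permutation_pvalue(rx, ry, n_perm=n_perm,
                               seed=int(rng.integers(2 ** 31 - 1)),
                               two_sided=two_sided, add_one=add_one)
        rho[i, j] = rho[j, i] = r
        p_raw[i, j] = p_raw[j, i] = p
    p_bonf = np.minimum(1.0, p_raw * n_pairs)
    significant = p_bonf < alpha
    significant[np.isnan(p_bonf)] = False
    np.fill_diagonal(significant, False)
    return PartialCorrelationResult(hm_names=list(hm_names),
                                    class_label=class_label, rho=rho,
                                    p_raw=p_raw, p_bonf=p_bonf,
                                    significant=significant, n_perm=n_perm,
                                    seed=seed, alpha=alpha)
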