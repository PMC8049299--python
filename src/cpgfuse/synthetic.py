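"""Synthetic promoter ChIP-seq data with planted TF-HM associations.

The generator emulates the statistical structure the association analysis
assumes: per-promoter CpG dinucleotide counts drawn from a bimodal
two-Gaussian mixture (CpG-poor vs CpG-rich promoter classes), log-normal
raw TF bin signals, and HM responses built as sparse, CpG-class-dependent
linear combinations of the log-unit-normalized TF bins plus Gaussian
noise.  Full ground truth (planted coefficients, true class labels, the
analytic class threshold) is carried along so recovery can be scored.

A single seed governs all draws through a fixed sub-stream order
(CpG counts, TF matrix, response noise), so regenerating any part of a
dataset with the same config is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .promoters import normalize_log_unit

POOR, RICH = "poor", "rich"
CLASSES = (POOR, RICH)

#: dict class-label -> list (one entry per HM) of {tf_index: length-k coefficient vector}
PlantedMap = dict


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    sd: float


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``planted`` maps each CpG class to one ``{tf_index: k-vector}`` dict per
    HM; coefficients act on the log-unit-normalized TF bins (the model's
    feature space), normalized within each class.  ``background`` is the
    (location, scale) of the Gaussian whose exponential gives raw TF bin
    signals.  ``noise_sd`` is on the response scale.
    """

    n_genes: int
    n_tfs: int
    n_bins: int = 10
    cpg_mixture: tuple[MixtureComponent, MixtureComponent] = (
        MixtureComponent(0.27, 20.0, 5.0),
        MixtureComponent(0.73, 60.0, 10.0),
    )
    planted: PlantedMap = field(default_factory=lambda: {POOR: [{}], RICH: [{}]})
    noise_sd: float = 0.1
    background: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    @property
    def n_hms(self) -> int:
        return len(self.planted[POOR])

    def validate(self) -> None:
        if self.n_bins < 1 or self.n_genes < 2 or self.n_tfs < 1:
            raise ValueError("need n_bins >= 1, n_genes >= 2, n_tfs >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        c1, c2 = self.cpg_mixture
        if abs(c1.weight + c2.weight - 1.0) > 1e-9:
            raise ValueError("mixture component weights must sum to 1")
        if c1.sd < 0 or c2.sd < 0 or min(c1.weight, c2.weight) < 0:
            raise ValueError("mixture sds and weights must be nonnegative")
        if set(self.planted) != set(CLASSES):
            raise ValueError(f"planted must have exactly the keys {CLASSES}")
        if len(self.planted[POOR]) != len(self.planted[RICH]):
            raise ValueError("planted must list the same number of HMs per class")
        for cls in CLASSES:
            for per_hm in self.planted[cls]:
                for tf, coefs in per_hm.items():
                    if not 0 <= tf < self.n_tfs:
                        raise ValueError(f"planted TF index {tf} out of range")
                    if len(np.atleast_1d(coefs)) != self.n_bins:
                        raise ValueError("planted coefficient vectors must have "
                                         f"length n_bins={self.n_bins}")

    def _streams(self) -> tuple[np.random.Generator, ...]:
        """Sub-streams in documented order: (cpg counts, tf matrix, noise)."""
        return tuple(np.random.default_rng(s)
                     for s in np.random.SeedSequence(self.seed).spawn(3))


@dataclass
class SyntheticTruth:
    planted: PlantedMap
    threshold: float
    labels: np.ndarray  # per-gene class label strings


@dataclass
class SyntheticDataset:
    tf_raw: np.ndarray     # gene x (m*k), nonnegative
    hm_raw: np.ndarray     # gene x n_hm, nonnegative
    cpg_counts: np.ndarray  # per-gene nonnegative int
    truth: SyntheticTruth
    config: SyntheticConfig

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene{i:05d}" for i in range(self.tf_raw.shape[0])]

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.config.n_tfs)]

    @property
    def hm_names(self) -> list[str]:
        return [f"HM{i}" for i in range(self.hm_raw.shape[1])]


def mixture_threshold(c1: MixtureComponent, c2: MixtureComponent) -> float:
    """Root of w1*N(x; mu1, sd1^2) = w2*N(x; mu2, sd2^2) between the means."""
    lo, hi = sorted((c1.mean, c2.mean))
    if hi - lo < 1e-12:
        return lo
    if c1.sd == 0 or c2.sd == 0:
        return 0.5 * (lo + hi)

    def diff(x):
        return (c1.weight * stats.norm.pdf(x, c1.mean, c1.sd)
                - c2.weight * stats.norm.pdf(x, c2.mean, c2.sd))

    # sample the open interval; brentq needs a sign change
    xs = np.linspace(lo, hi, 512)[1:-1]
    vals = diff(xs)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise ValueError("no density-equality root between the component means")
    i = idx[0]
    return float(optimize.brentq(diff, xs[i], xs[i + 1], xtol=1e-12))


def generate_cpg_counts(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-gene CpG counts from the two-Gaussian mixture.

    Returns (counts, labels): counts are rounded to the nearest integer and
    truncated at 0; labels name the generating component, with the
    lower-mean component mapped to "poor".
    """
    config.validate()
    rng = config._streams()[0]
    c1, c2 = config.cpg_mixture
    comp = rng.random(config.n_genes) >= c1.weight  # False -> comp 1, True -> comp 2
    means = np.where(comp, c2.mean, c1.mean)
    sds = np.where(comp, c2.sd, c1.sd)
    counts = np.maximum(0, np.rint(rng.normal(means, sds))).astype(int)
    low_first = c1.mean <= c2.mean
    labels = np.where(comp, RICH if low_first else POOR,
                      POOR if low_first else RICH)
    return counts, labels


def generate_tf_signals(config: SyntheticConfig) -> np.ndarray:
    """Log-normal raw TF bin signals, gene x (m*k), TF-major bin-minor order."""
    config.validate()
    rng = config._streams()[1]
    loc, scale = config.background
    if scale < 0:
        raise ValueError("background scale must be >= 0")
    z = rng.normal(loc, scale, (config.n_genes, config.n_tfs * config.n_bins))
    return np.exp(z)


def _normalized_features(tf_raw: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Per-class, per-column log-unit normalization of the raw TF bins."""
    return np.column_stack([normalize_log_unit(tf_raw[rows, j])
                            for j in range(tf_raw.shape[1])])


def generate_hm_response(tf_raw: np.ndarray, cpg_labels: np.ndarray,
                         config: SyntheticConfig) -> np.ndarray:
    """Build HM responses from the planted class-specific linear models.

    For each gene the response is the planted linear combination of the
    class's log-unit-normalized TF bins (normalization computed within the
    class) plus N(0, noise_sd^2) noise; each HM column is then shifted so
    its minimum is 0, matching raw-signal semantics.
    """
    config.validate()
    m, k = config.n_tfs, config.n_bins
    if tf_raw.shape != (config.n_genes, m * k):
        raise ValueError("tf_raw shape inconsistent with config")
    if not set(np.unique(cpg_labels)) <= set(CLASSES):
        raise ValueError(f"labels must be in {CLASSES}")
    rng = config._streams()[2]
    n_hm = config.n_hms
    y = np.zeros((config.n_genes, n_hm))
    for cls in CLASSES:
        rows = np.nonzero(cpg_labels == cls)[0]
        if len(rows) == 0:
            continue
        Xn = _normalized_features(tf_raw, rows)
        for h, per_hm in enumerate(config.planted[cls]):
            signal = np.zeros(len(rows))
            for tf, coefs in per_hm.items():
                block = Xn[:, tf * k:(tf + 1) * k]
                signal += block @ np.asarray(coefs, dtype=float)
            y[rows, h] = signal
    y += rng.normal(0.0, config.noise_sd, y.shape) if config.noise_sd > 0 else 0.0
    y -= y.min(axis=0, keepdims=True)
    return y


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Compose counts, TF signals and responses into one dataset with truth."""
    config.validate()
    counts, labels = generate_cpg_counts(config)
    tf_raw = generate_tf_signals(config)
    hm_raw = generate_hm_response(tf_raw, labels, config)
    c1, c2 = config.cpg_mixture
    try:
        thr = mixture_threshold(c1, c2)
    except ValueError:
        thr = 0.5 * (c1.mean + c2.mean)
    truth = SyntheticTruth(planted=config.planted, threshold=thr, labels=labels)
    return SyntheticDataset(tf_raw=tf_raw, hm_raw=hm_raw, cpg_counts=counts,
                            truth=truth, config=config)


def noise_sd_for_r2(config: SyntheticConfig, r2: float) -> float:
    """Noise standard deviation targeting a within-class R^2 for the
    planted signal, from the pooled within-class signal variance of the
    noiseless construction."""
    import dataclasses

    if not 0 < r2 < 1:
        raise ValueError("r2 must lie in (0, 1)")
    noiseless = dataclasses.replace(config, noise_sd=0.0)
    _, labels = generate_cpg_counts(noiseless)
    tf_raw = generate_tf_signals(noiseless)
    y = generate_hm_response(tf_raw, labels, noiseless)
    num, den = 0.0, 0
    for cls in CLASSES:
        rows = labels == cls
        n_rows = int(rows.sum())
        if n_rows < 2:
            continue
        for h in range(y.shape[1]):
            num += float(y[rows, h].var()) * n_rows
            den += n_rows
    var = num / max(den, 1)
    return float(np.sqrt(var * (1.0 - r2) / r2))


def block_coefficients(k: int, start: int, stop: int, value: float) -> np.ndarray:
    """Convenience: a length-k vector equal to ``value`` on bins [start, stop)."""
    v = np.zeros(k)
    v[start:stop] = value
    return v
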