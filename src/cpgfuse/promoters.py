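"""Promoter windows, signal binning and CpG-content stratification.

Promoters are strand-aware windows around the TSS (default 500 bp up- and
downstream, tiled by equal 100-bp bins).  Bin index 0 is always the most
upstream bin in *gene* orientation, so minus-strand windows are
bin-reversed relative to genome coordinates.  Coordinates are 0-based
half-open (BED convention) throughout; GTF input is converted on read.

CpG content is the number of CG dinucleotides in the window.  Across
protein-coding promoters this count is bimodal; a two-component Gaussian
mixture is fitted and the intersection of the two weighted component
densities between their means defines the threshold splitting CpG-poor
from CpG-rich promoters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

POOR, RICH = "poor", "rich"


# ---------------------------------------------------------------------------
# Promoter windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterRegion:
    """Strand-aware promoter window with equal-width bin boundaries.

    ``window`` is the half-open genomic interval [tss-up, tss+down) for +
    genes and [tss-down, tss+up) for - genes; ``bin_edges`` holds k+1
    genomic coordinates.  Bin 0 is the most upstream bin in gene
    orientation (the genomically rightmost for minus-strand genes).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int
    k: int
    excluded: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.k + 1).astype(int)

    @property
    def bin_width(self) -> int:
        return self.length // self.k


def define_promoter_windows(records, up: int = 500, down: int = 500,
                            k: int = 10) -> list[PromoterRegion]:
    """One promoter region per gene from (gene_id, chrom, tss, strand) records.

    ``records`` is an iterable of mappings or 4-tuples.  Windows extending
    below coordinate 0 are clipped to 0 and flagged ``excluded``; duplicate
    gene ids are rejected.
    """
    if (up + down) % k != 0:
        raise ValueError("window length up+down must be divisible by k")
    seen: set[str] = set()
    out = []
    for rec in records:
        if isinstance(rec, dict):
            gid, chrom, tss, strand = (rec["gene_id"], rec["chrom"],
                                       int(rec["tss"]), rec.get("strand"))
        else:
            gid, chrom, tss, strand = rec[0], rec[1], int(rec[2]), rec[3]
        if strand not in ("+", "-"):
            raise ValueError(f"{gid}: missing or invalid strand {strand!r}")
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid}")
        seen.add(gid)
        if strand == "+":
            start, end = tss - up, tss + down
        else:
            start, end = tss - down, tss + up
        excluded = start < 0
        if excluded:
            logger.warning("gene %s: window extends below 0, flagged excluded", gid)
            start = 0
        out.append(PromoterRegion(gene_id=gid, chrom=chrom, tss=tss,
                                  strand=strand, start=start, end=end, k=k,
                                  excluded=excluded))
    return out


def read_bed6(path) -> list[dict]:
    """BED6 records as window definitions: TSS = start for +, end for - genes."""
    recs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns")
            start, end, strand = int(f[1]), int(f[2]), f[5]
            tss = start if strand == "+" else end - 1
            recs.append(dict(gene_id=f[3], chrom=f[0], tss=tss, strand=strand))
    return recs


def read_gtf_tss(path) -> list[dict]:
    """Gene TSS records from a GTF: the most 5' transcript start per gene.

    GTF is 1-based closed; the TSS is converted to a 0-based coordinate.
    For + genes the most 5' TSS is the smallest start, for - genes the
    largest end.
    """
    best: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("transcript", "gene"):
                continue
            attrs = f[8]
            gid = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gid = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gid is None:
                continue
            strand = f[6]
            start1, end1 = int(f[3]), int(f[4])
            tss = start1 - 1 if strand == "+" else end1 - 1
            cur = best.get(gid)
            if cur is None:
                best[gid] = dict(gene_id=gid, chrom=f[0], tss=tss, strand=strand)
            else:
                if strand == "+":
                    cur["tss"] = min(cur["tss"], tss)
                else:
                    cur["tss"] = max(cur["tss"], tss)
    return list(best.values())


# ---------------------------------------------------------------------------
# Signal aggregation and normalization
# ---------------------------------------------------------------------------

def bin_signal(coverage: np.ndarray, region: PromoterRegion) -> np.ndarray:
    """Mean per-bin coverage in gene orientation.

    ``coverage`` runs along genome coordinates over the window; for
    minus-strand regions the bin order is reversed so bin 0 is the most
    upstream bin of the gene.
    """
    coverage = np.asarray(coverage, dtype=float)
    if coverage.size != region.length:
        raise ValueError(f"coverage length {coverage.size} != window "
                         f"length {region.length}")
    if region.length % region.k != 0:
        raise ValueError("window length not divisible by bin count")
    means = coverage.reshape(region.k, -1).mean(axis=1)
    return means[::-1] if region.strand == "-" else means


def aggregate_response(coverage: np.ndarray,
                       region: PromoterRegion | None = None) -> float:
    """Window-mean signal: the HM response value for one gene."""
    coverage = np.asarray(coverage, dtype=float)
    if region is not None and coverage.size != region.length:
        raise ValueError("coverage length does not match window")
    return float(coverage.mean())


def normalize_log_unit(values: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Map nonnegative signals to [0, 1] via log(value + pseudocount).

    The log-transformed column is min-max scaled; constant columns map to
    all-zeros (they carry no information).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative input to normalize_log_unit")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.log(values + pseudocount)
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# CpG counting and the bimodal split
# ---------------------------------------------------------------------------

def count_cpg(sequence: str, bin_width: int = 5,
              expected_length: int | None = None) -> tuple[int, np.ndarray]:
    """Count CG dinucleotides in a window, plus a per-bin profile.

    A CG straddling a profile-bin boundary is assigned to the bin of its C.
    Returns (total, profile).
    """
    seq = sequence.upper()
    if expected_length is not None and len(seq) != expected_length:
        raise ValueError(f"sequence length {len(seq)} != expected {expected_length}")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n_bins = max(1, -(-len(seq) // bin_width))
    profile = np.zeros(n_bins, dtype=int)
    pos = seq.find("CG")
    while pos != -1:
        profile[pos // bin_width] += 1
        pos = seq.find("CG", pos + 1)
    return int(profile.sum()), profile


@dataclass
class CpGPartition:
    """Two-Gaussian fit of per-gene CpG counts and the resulting class split."""

    counts: np.ndarray
    gauss1: tuple[float, float, float]  # (weight, mean, sd), mean1 < mean2
    gauss2: tuple[float, float, float]
    threshold: float
    labels: np.ndarray  # per-gene "poor"/"rich"

    @property
    def n_poor(self) -> int:
        return int(np.sum(self.labels == POOR))

    @property
    def n_rich(self) -> int:
        return int(np.sum(self.labels == RICH))


def fit_bimodal_split(counts: np.ndarray, *, n_init: int = 10,
                      seed: int = 0) -> CpGPartition:
    """Fit a two-Gaussian mixture to CpG counts and split at the density
    intersection.

    EM (k-means initialized, ``n_init`` restarts, fixed seed) fits the
    mixture on the raw per-gene totals.  The threshold is the root of
    w1*N(x; mu1, s1^2) = w2*N(x; mu2, s2^2) inside (mu1, mu2); genes with
    count < threshold are CpG-poor, the rest CpG-rich.
    """
    from sklearn.mixture import GaussianMixture

    counts = np.asarray(counts, dtype=float).ravel()
    if np.unique(counts).size < 2:
        raise ValueError("need at least 2 distinct count values")
    gm = GaussianMixture(n_components=2, n_init=n_init, init_params="kmeans",
                         random_state=seed)
    gm.fit(counts[:, None])
    w = gm.weights_.ravel()
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    if min(w) < 1e-6 or min(sd) < 1e-9:
        raise ValueError("degenerate mixture fit: vanishing component "
                         f"(weights {w}, sds {sd})")
    if mu[1] - mu[0] < 1e-9:
        raise ValueError("mixture components collapsed to one mode")

    def diff(x):
        return (w[0] * stats.norm.pdf(x, mu[0], sd[0])
                - w[1] * stats.norm.pdf(x, mu[1], sd[1]))

    xs = np.linspace(mu[0], mu[1], 1024)[1:-1]
    vals = diff(xs)
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(idx) == 0:
        raise ValueError("no density-equality root between the component means")
    thr = float(optimize.brentq(diff, xs[idx[0]], xs[idx[0] + 1], xtol=1e-10))
    labels = np.where(counts < thr, POOR, RICH)
    return CpGPartition(counts=counts.astype(int),
                        gauss1=(float(w[0]), float(mu[0]), float(sd[0])),
                        gauss2=(float(w[1]), float(mu[1]), float(sd[1])),
                        threshold=thr, labels=labels)


# ---------------------------------------------------------------------------
# Signal bundle
# ---------------------------------------------------------------------------

@dataclass
class SignalBundle:
    """Aligned per-gene TF bin features and HM window-mean responses.

    ``X_norm``/``y_norm`` are the per-column log-unit-normalized versions of
    the raw matrices; the normalization scope (which genes a column's
    min/max is computed over) is decided by the caller, typically within
    one CpG class.
    """

    genes: list[str]
    tf_names: list[str]
    hm_names: list[str]
    bin_count: int
    X_raw: np.ndarray
    y_raw: np.ndarray
    X_norm: np.ndarray | None = None
    y_norm: np.ndarray | None = None

    def __post_init__(self):
        if self.X_raw.shape[0] != self.y_raw.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X_raw.shape[1] != len(self.tf_names) * self.bin_count:
            raise ValueError("X column count != n_tfs * bin_count")

    def normalize(self, pseudocount: float = 1.0,
                  normalize_response: bool = True) -> "SignalBundle":
        """Fill X_norm / y_norm by per-column log-unit normalization."""
        self.X_norm = np.column_stack(
            [normalize_log_unit(self.X_raw[:, j], pseudocount)
             for j in range(self.X_raw.shape[1])])
        if normalize_response:
            self.y_norm = np.column_stack(
                [normalize_log_unit(self.y_raw[:, j], pseudocount)
                 for j in range(self.y_raw.shape[1])])
        else:
            self.y_norm = self.y_raw.copy()
        return self

    def subset(self, rows: np.ndarray) -> "SignalBundle":
        """Row subset (raw matrices only; re-normalize within the subset)."""
        genes = [self.genes[i] for i in np.nonzero(rows)[0]] \
            if rows.dtype == bool else [self.genes[i] for i in rows]
        return SignalBundle(genes=genes, tf_names=self.tf_names,
                            hm_names=self.hm_names, bin_count=self.bin_count,
                            X_raw=self.X_raw[rows], y_raw=self.y_raw[rows])
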