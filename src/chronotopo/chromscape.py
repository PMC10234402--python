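"""Chromosome-wide landscapes of gene age, expression and methylation.

Reproduces the binned-track analysis used for chromosome-scale genomes:
RPKM in fixed 200 bp bins, per-chromosome nonparametric smoothing of gene
age and expression along the chromosome, a genome-wide gene-age
permutation null with per-chromosome paired t-tests, detection of "young
regions" (loci jointly enriched for young genes and highly expressed small
RNA loci), per-gene age-expression correlation, and filtering of highly
methylated CG sites.

The smoother is a penalized cubic B-spline (P-spline): basis dimension 10,
second-order difference penalty on the coefficients, penalty weight chosen
by generalized cross-validation. Linear trends sit in the penalty null
space, so the fit shrinks toward a straight line as the penalty grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 200


@dataclass
class SmoothConfig:
    """Settings of the per-chromosome spline smoother."""

    basis_dimension: int = 10
    penalty_order: int = 2
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-4, 8, 25))

    def __post_init__(self):
        if self.basis_dimension < 4:
            raise ValueError("basis_dimension must be >= 4 for a cubic spline")


@dataclass
class PermutationResult:
    chrom: str
    t_statistic: float
    p_value: float
    p_adjusted: float
    n_permutations: int
    seed: int


@dataclass
class YoungRegion:
    chrom: str
    start: int
    end: int
    mean_smoothed_rank: float
    mean_srna_rpkm: float


# ---------------------------------------------------------------------------
# binning

def bin_rpkm(
    intervals: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    total_mapped: Optional[int] = None,
    ignore_duplicates: bool = True,
) -> pd.DataFrame:
    """RPKM of read intervals in fixed-width bins tiling each chromosome.

    intervals needs columns chrom, start, end (0-based half-open). Each
    read contributes overlap_bp/read_length to every bin it overlaps, so
    bin counts sum exactly to the number of reads. Per bin,
    RPKM = count / ((bin_len/1000) * (total_mapped/1e6)); total_mapped
    defaults to the number of input intervals. Exact duplicate intervals
    are dropped by default (one representative kept).

    Returns a frame with chrom, bin_start, bin_size (actual, last bin may
    be short), count, rpkm.
    """
    req = {"chrom", "start", "end"}
    if not req.issubset(intervals.columns):
        raise ValueError(f"intervals must have columns {req}")
    iv = intervals.copy()
    if ignore_duplicates:
        iv = iv.drop_duplicates(subset=["chrom", "start", "end"])
    for r in iv.itertuples():
        if r.chrom not in chrom_sizes:
            raise ValueError(f"interval on unknown chromosome {r.chrom}")
        if r.start < 0 or r.end > chrom_sizes[r.chrom] or r.end <= r.start:
            raise ValueError(
                f"interval out of bounds: {r.chrom}:{r.start}-{r.end} "
                f"(size {chrom_sizes[r.chrom]})"
            )
    if total_mapped is None:
        total_mapped = len(iv)
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")

    counts: dict[str, np.ndarray] = {
        c: np.zeros(-(-size // bin_size)) for c, size in chrom_sizes.items()
    }
    for r in iv.itertuples():
        length = r.end - r.start
        b0 = r.start // bin_size
        b1 = (r.end - 1) // bin_size
        if b0 == b1:
            counts[r.chrom][b0] += 1.0
        else:
            for b in range(b0, b1 + 1):
                lo = max(r.start, b * bin_size)
                hi = min(r.end, (b + 1) * bin_size)
                counts[r.chrom][b] += (hi - lo) / length

    rows = []
    scale = total_mapped / 1e6
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for b, cnt in enumerate(counts[chrom]):
            start = b * bin_size
            blen = min(bin_size, size - start)
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": start,
                    "bin_size": blen,
                    "count": float(cnt),
                    "rpkm": float(cnt) / ((blen / 1000.0) * scale),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# smoothing

class _SplineBasis:
    """Cubic B-spline basis with a difference penalty on one chromosome."""

    def __init__(self, x: np.ndarray, cfg: SmoothConfig):
        k = cfg.basis_dimension
        degree = 3
        lo, hi = float(np.min(x)), float(np.max(x))
        span = hi - lo if hi > lo else 1.0
        n_inner = k - degree + 1
        inner = np.linspace(lo, hi, n_inner)
        t = np.concatenate([[lo - span * 1e-6] * degree, inner, [hi + span * 1e-6] * degree])
        self.t, self.degree = t, degree
        self.B = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
        D = np.diff(np.eye(k), n=cfg.penalty_order, axis=0)
        self.P = D.T @ D
        self.BtB = self.B.T @ self.B
        self.cfg = cfg
        # per-lambda solve operators and effective dof
        self.A = {}
        self.edf = {}
        for lam in cfg.lambda_grid:
            Ainv = np.linalg.solve(self.BtB + lam * self.P, self.B.T)
            self.A[lam] = Ainv
            # trace of the hat matrix B @ Ainv without forming it
            self.edf[lam] = float(np.einsum("ij,ji->", self.B, Ainv))

    def fit_many(self, Y: np.ndarray) -> np.ndarray:
        """GCV-selected fits for each column of Y (n_points x n_series)."""
        n = self.B.shape[0]
        best_fit = None
        best_gcv = None
        for lam in self.cfg.lambda_grid:
            fit = self.B @ (self.A[lam] @ Y)
            rss = np.sum((Y - fit) ** 2, axis=0)
            denom = max(n - self.edf[lam], 1e-8)
            gcv = n * rss / denom**2
            if best_fit is None:
                best_fit, best_gcv = fit.copy(), gcv
            else:
                better = gcv < best_gcv
                best_fit[:, better] = fit[:, better]
                best_gcv = np.minimum(best_gcv, gcv)
        return best_fit


def smooth_track(
    x: Sequence[float], y: Sequence[float], cfg: Optional[SmoothConfig] = None
) -> np.ndarray:
    """Penalized-spline fit of y on x, returning fitted values at the
    input positions. Falls back to an ordinary linear fit when there are
    fewer distinct positions than basis functions (logged)."""
    cfg = cfg or SmoothConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n_distinct = np.unique(x).size
    if n_distinct < cfg.basis_dimension:
        logger.info("only %d distinct positions; falling back to linear fit", n_distinct)
        if n_distinct < 2:
            return np.full_like(y, y.mean())
        coef = np.polyfit(x, y, 1)
        return np.polyval(coef, x)
    order = np.argsort(x, kind="stable")
    basis = _SplineBasis(x[order], cfg)
    fitted_sorted = basis.fit_many(y[order][:, None])[:, 0]
    out = np.empty_like(fitted_sorted)
    out[order] = fitted_sorted
    return out


# ---------------------------------------------------------------------------
# permutation test

def permute_ages_test(
    genes: pd.DataFrame,
    cfg: Optional[SmoothConfig] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[PermutationResult], pd.DataFrame]:
    """Genome-wide gene-age permutation null with per-chromosome t-tests.

    genes needs columns chrom, start, phylorank. Ages are permuted across
    all genes genome-wide (positions fixed); per gene the mean permuted
    age is recorded. Per chromosome, a paired t-test compares the observed
    gene ages with the permutation-mean age at the same gene positions —
    effectively asking whether the chromosome's age composition departs
    from what genome-wide reshuffling predicts. The smoothed observed
    profile and the smoothed permutation-mean profile are returned for
    plotting. P-values are Benjamini-Hochberg adjusted across chromosomes.

    Pairing raw (not smoothed) values keeps the test calibrated: smoothed
    residuals are strongly correlated along a chromosome, which wrecks the
    t-test's nominal level.

    Returns (results, frame) where frame carries per-gene chrom, start,
    observed_fit and permuted_mean_fit.
    """
    cfg = cfg or SmoothConfig()
    req = {"chrom", "start", "phylorank"}
    if not req.issubset(genes.columns):
        raise ValueError(f"genes must have columns {req}")
    chroms = sorted(genes.chrom.unique())
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes for the grouped test")

    g = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    ages = g.phylorank.to_numpy(dtype=float)
    n_genes = len(g)

    rng = np.random.default_rng(seed)
    perm_sum = np.zeros(n_genes)
    for _ in range(n_perm):
        perm_sum += ages[rng.permutation(n_genes)]
    perm_mean_age = perm_sum / n_perm

    observed = np.empty(n_genes)
    perm_mean = np.empty(n_genes)
    results = []
    pvals = []
    for chrom in chroms:
        mask = (g.chrom == chrom).to_numpy()
        x = g.start.to_numpy(dtype=float)[mask]
        n_distinct = np.unique(x).size
        if n_distinct < cfg.basis_dimension:
            raise ValueError(
                f"chromosome {chrom} has {n_distinct} distinct gene positions; "
                f"need >= basis_dimension ({cfg.basis_dimension})"
            )
        observed[mask] = smooth_track(x, ages[mask], cfg)
        perm_mean[mask] = smooth_track(x, perm_mean_age[mask], cfg)

        diffs = ages[mask] - perm_mean_age[mask]
        t_stat = _paired_t(diffs)
        if t_stat is None:
            logger.info("chromosome %s: zero-variance paired differences; p=1", chrom)
            t_stat, p = 0.0, 1.0
        elif not np.isfinite(t_stat):
            p = 0.0  # constant nonzero shift: certain departure
        else:
            _, p = stats.ttest_rel(ages[mask], perm_mean_age[mask])
        results.append(
            PermutationResult(
                chrom=chrom, t_statistic=float(t_stat), p_value=float(p),
                p_adjusted=np.nan, n_permutations=n_perm, seed=seed,
            )
        )
        pvals.append(float(p))

    for res, padj in zip(results, bh_adjust(pvals)):
        res.p_adjusted = float(padj)

    frame = pd.DataFrame(
        {
            "chrom": g.chrom,
            "start": g.start,
            "phylorank": g.phylorank,
            "observed_fit": observed,
            "permuted_mean_fit": perm_mean,
        }
    )
    return results, frame


def _paired_t(diffs: np.ndarray) -> Optional[float]:
    """Paired t-statistic of a difference vector; None when degenerate."""
    n = diffs.size
    if n < 2:
        return None
    sd = diffs.std(ddof=1)
    if not sd > 0 or np.allclose(diffs, diffs[0]):
        return None if np.allclose(diffs, 0.0) else float(np.sign(diffs.mean()) * np.inf)
    return float(diffs.mean() / (sd / np.sqrt(n)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# region detection, correlation, methylation

def detect_young_regions(
    track: pd.DataFrame,
    rank_quantile: float = 0.9,
    srna_quantile: float = 0.9,
    merge_gap_bp: int = 100_000,
    min_len_bp: int = 200_000,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[YoungRegion]:
    """Loci jointly enriched for young genes and small-RNA expression.

    track needs columns chrom, pos, smoothed_rank, srna_rpkm on a common
    set of positions. Positions exceeding both genome-wide quantile
    thresholds are merged when within merge_gap_bp; merged regions shorter
    than min_len_bp are dropped. Output is sorted by (chrom, start) and
    independent of input row order.
    """
    for q in (rank_quantile, srna_quantile):
        if not 0.0 < q < 1.0:
            raise ValueError("quantile thresholds must lie in (0, 1)")
    req = {"chrom", "pos", "smoothed_rank", "srna_rpkm"}
    if not req.issubset(track.columns):
        raise ValueError(f"track must have columns {req}")
    t = track.sort_values(["chrom", "pos"], kind="stable")
    rank_thr = t.smoothed_rank.quantile(rank_quantile)
    srna_thr = t.srna_rpkm.quantile(srna_quantile)
    # a threshold equal to the track minimum means the track is flat at the
    # quantile level: there is no enrichment to call
    if rank_thr <= t.smoothed_rank.min() or srna_thr <= t.srna_rpkm.min():
        return []
    hot = t[(t.smoothed_rank >= rank_thr) & (t.srna_rpkm >= srna_thr)]
    regions: list[YoungRegion] = []
    for chrom, sub in hot.groupby("chrom", sort=True):
        pos = sub.pos.to_numpy()
        runs: list[list[int]] = [[int(pos[0])]]
        for p in pos[1:]:
            if p - runs[-1][-1] <= merge_gap_bp:
                runs[-1].append(int(p))
            else:
                runs.append([int(p)])
        for run in runs:
            start, end = run[0], run[-1] + bin_size
            if end - start < min_len_bp:
                continue
            inside = t[(t.chrom == chrom) & (t.pos >= start) & (t.pos < end)]
            regions.append(
                YoungRegion(
                    chrom=str(chrom), start=start, end=end,
                    mean_smoothed_rank=float(inside.smoothed_rank.mean()),
                    mean_srna_rpkm=float(inside.srna_rpkm.mean()),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def per_gene_age_expression_corr(
    genes: pd.DataFrame, method: str = "spearman"
) -> tuple[float, float]:
    """Rank correlation between per-gene age and expression.

    genes needs columns phylorank and srna_rpkm with >= 10 defined rows.
    Returns (coefficient, p). Constant input yields (nan, nan), logged.
    """
    sub = genes[["phylorank", "srna_rpkm"]].dropna()
    if len(sub) < 10:
        raise ValueError("need >= 10 genes with defined age and expression")
    x = sub.phylorank.to_numpy(dtype=float)
    y = sub.srna_rpkm.to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input: correlation undefined")
        return float("nan"), float("nan")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def filter_high_methylation(
    meth: pd.DataFrame, threshold_pct: float = 80.0
) -> pd.DataFrame:
    """Keep CG positions with 5mC strictly above the threshold (percent).

    meth needs columns chrom, pos, meth_pct. Fractions in [0, 1] are
    auto-detected and rescaled to percent (logged). Rows outside [0, 100]
    are dropped with a warning.
    """
    req = {"chrom", "pos", "meth_pct"}
    if not req.issubset(meth.columns):
        raise ValueError(f"methylation table must have columns {req}")
    m = meth.copy()
    if len(m) and m.meth_pct.max() <= 1.0:
        logger.info("methylation values look like fractions; rescaling to percent")
        m["meth_pct"] = m.meth_pct * 100.0
    bad = (m.meth_pct < 0) | (m.meth_pct > 100)
    if bad.any():
        logger.warning("dropping %d methylation rows outside [0, 100]", int(bad.sum()))
        m = m[~bad]
    return m[m.meth_pct > threshold_pct].reset_index(drop=True)
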