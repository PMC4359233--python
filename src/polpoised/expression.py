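"""Expression-matrix normalization and differential expression.

Covers quantile normalization, the empirical-Bayes moderated t-test with
method-of-moments hyperparameter estimation, per-gene standardization,
multi-cohort merging on the common gene set, quantile stratification of
samples by a marker gene, and the ddCt qPCR fold-change transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

DIRECTION_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class DEConfig:
    alpha: float = 0.05
    top_k: int | None = None
    prior_df: float | None = None       # d0; None -> estimate
    prior_var: float | None = None      # s0^2; None -> estimate
    stratify_quantile: float = 0.35
    adjust_bh: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.stratify_quantile <= 0.5:
            raise ValueError("stratify_quantile must be in (0, 0.5]")
        if self.prior_df is not None and self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")


class ExpressionMatrix:
    """Genes x samples matrix with per-sample group/cohort labels.

    Gene identifiers are uppercased and stripped on construction so that
    cross-cohort matching is by normalized symbol.
    """

    def __init__(self, values: pd.DataFrame, labels: pd.Series | None = None):
        values = values.copy()
        values.index = values.index.astype(str).str.strip().str.upper()
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids after normalization")
        self.values = values
        if labels is None:
            labels = pd.Series("all", index=values.columns)
        self.labels = labels.reindex(values.columns)
        if self.labels.isna().any():
            raise ValueError("every sample needs a label")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.labels.copy())

    def to_tsv(self, path) -> None:
        """Two-row header: sample ids then labels, one gene per row."""
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(map(str, self.sample_ids)) + "\n")
            fh.write("label\t" + "\t".join(map(str, self.labels)) + "\n")
            self.values.to_csv(fh, sep="\t", header=False)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        head = pd.read_csv(path, sep="\t", nrows=1, index_col=0)
        labels = head.iloc[0]
        values = pd.read_csv(path, sep="\t", skiprows=[1], index_col=0)
        labels.index = values.columns
        return cls(values, pd.Series(labels.to_numpy(), index=values.columns))


def quantile_normalize(matrix):
    """Force every column onto the mean of the sorted columns.

    Tied values within a column receive the mean of the target values at
    the tied ranks.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = df.to_numpy(dtype=float)
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        col = np.empty_like(target)
        # tied input values share the mean of their target values
        vals = x[order, j]
        _, inv, counts = np.unique(vals, return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=target)
        col[order] = (sums / counts)[inv]
        out[:, j] = col
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(res, matrix.labels)
    return res


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-10):
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to the scaled-F model of the
    sample variances, via digamma/trigamma matching on log s2.

    Returns (d0, s0sq); d0 may be inf when the variances are under-dispersed
    relative to chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive sample variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return math.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * float(_trigamma_inverse(np.array(evar)))
    s0sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0sq


def moderated_t(
    matrix,
    group_labels=None,
    config: DEConfig | None = None,
    *,
    group_pos: str | None = None,
    group_neg: str | None = None,
) -> pd.DataFrame:
    """Two-group empirical-Bayes moderated t-test.

    logFC = mean(positive group) - mean(negative group). The pooled
    per-gene variance is shrunk toward the prior,
    s2_tilde = (d0*s0^2 + d*s2)/(d0 + d), and the t statistic is referred
    to d0 + d degrees of freedom. With d0 = 0 this is the ordinary pooled
    two-sample t; d0 = inf uses s0^2 for every gene.

    Returns a DataFrame indexed by gene_id with columns
    logFC, t_mod, p, direction, significant.
    """
    config = config or DEConfig()
    if isinstance(matrix, ExpressionMatrix):
        df = matrix.values
        labels = matrix.labels if group_labels is None else pd.Series(
            group_labels, index=df.columns
        )
    else:
        df = matrix
        labels = pd.Series(np.asarray(group_labels), index=df.columns)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    if group_pos is None:
        group_pos, group_neg = groups[0], groups[1]
    elif group_neg is None:
        group_neg = [g for g in groups if g != group_pos][0]
    a = df.loc[:, labels == group_pos].to_numpy(dtype=float)
    b = df.loc[:, labels == group_neg].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    d_resid = n1 + n2 - 2
    logfc = a.mean(axis=1) - b.mean(axis=1)
    s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / d_resid

    keep = np.isfinite(s2)
    zero_var = s2 <= 0
    if zero_var.any():
        logger.warning("%d genes with zero residual variance excluded", zero_var.sum())
        keep &= ~zero_var

    d0, s0sq = config.prior_df, config.prior_var
    if d0 is None or s0sq is None:
        d0_est, s0_est = estimate_prior(s2[keep], d_resid)
        d0 = d0_est if d0 is None else d0
        s0sq = s0_est if s0sq is None else s0sq

    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = math.inf
    else:
        s2_tilde = (d0 * s0sq + d_resid * s2) / (d0 + d_resid)
        df_total = d0 + d_resid
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    direction = np.where(
        np.abs(logfc) <= DIRECTION_ZERO_TOL, "zero", np.where(logfc > 0, "up", "down")
    )
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "t_mod": t_mod,
            "p": p,
            "direction": direction,
        },
        index=df.index,
    )
    out = out[keep]
    pvals = out["p"].to_numpy()
    if config.adjust_bh:
        pvals = _bh_adjust(pvals)
        out["p_adj"] = pvals
    out["significant"] = pvals < config.alpha
    out.attrs["d0"] = float(d0)
    out.attrs["s0sq"] = float(s0sq)
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_significant(de: pd.DataFrame, alpha: float = 0.05, top_k: int | None = None):
    """Gene set selection; by p < alpha, or the top_k smallest p when given.

    Returns (gene Index, mode_agreement flag); the flag is False when
    top_k and the alpha cut disagree.
    """
    by_alpha = de.index[de["p"] < alpha]
    if top_k is None:
        return by_alpha, True
    by_rank = de["p"].nsmallest(top_k).index
    agree = set(by_alpha) == set(by_rank)
    if not agree:
        logger.info(
            "top-%d selection (%d genes) differs from p<%g selection (%d genes)",
            top_k, len(by_rank), alpha, len(by_alpha),
        )
    return by_rank, agree


def standardize_genes(matrix, *, ddof: int = 1):
    """Center every gene row to mean 0 and scale to sd 1 (sample sd by
    default; ddof=0 for the population convention). Constant rows are
    dropped with a warning."""
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=ddof)
    const = sd == 0
    if const.any():
        logger.warning("%d constant gene rows excluded from standardization", const.sum())
    xk = x[~const]
    z = (xk - xk.mean(axis=1, keepdims=True)) / sd[~const, None]
    res = pd.DataFrame(z, index=df.index[~const], columns=df.columns)
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(res, matrix.labels)
    return res


def merge_cohorts(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate cohorts on the intersection of normalized gene ids."""
    if len(matrices) < 2:
        raise ValueError("need >= 2 cohorts to merge")
    common = matrices[0].gene_ids
    for m in matrices[1:]:
        common = common.intersection(m.gene_ids)
    if len(common) == 0:
        raise ValueError("no common genes across cohorts")
    common = common.sort_values()
    values = pd.concat([m.values.loc[common] for m in matrices], axis=1)
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample ids across cohorts")
    labels = pd.concat([m.labels for m in matrices])
    return ExpressionMatrix(values, labels)


def stratify_by_gene(matrix: ExpressionMatrix, gene_id: str, q: float = 0.35):
    """Split samples into the top-q and bottom-q fractions by one gene's
    expression; the middle is discarded.

    Returns (positive sample Index, negative sample Index), each of size
    floor(q * n). Ties are broken by stable sample order.
    """
    gene_id = gene_id.strip().upper()
    if gene_id not in matrix.gene_ids:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    n = len(matrix.sample_ids)
    k = int(math.floor(q * n))
    if k < 1:
        raise ValueError("stratum size floor(q*n) < 1")
    vals = matrix.values.loc[gene_id].to_numpy(dtype=float)
    order = np.argsort(vals, kind="mergesort")
    neg = matrix.sample_ids[order[:k]]
    pos = matrix.sample_ids[order[n - k:]]
    return pos, neg


def ddct_fold_change(
    ct_target_a: float, ct_ref_a: float, ct_target_b: float, ct_ref_b: float
) -> float:
    """qPCR relative quantification: 2**(-ddCt) of condition A vs B."""
    for v in (ct_target_a, ct_ref_a, ct_target_b, ct_ref_b):
        if v <= 0 or not np.isfinite(v):
            raise ValueError("Ct values must be positive finite numbers")
    ddct = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return float(2.0 ** (-ddct))
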