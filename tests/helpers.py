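"""Independent oracle implementations used only by the tests.

These deliberately re-derive results through different code paths than
the package (explicit loops, direct formulas, numerical integration) so
agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def brute_force_site_calls(gene_probes, *, alpha_central=0.05, strict=0.05,
                           relax=0.10, window=1100):
    """Loop-based re-implementation of the probe-triple rule for one gene.

    ``gene_probes`` is a list of (probe_id, offset, p_probe) tuples in any
    order. Returns {central_probe_id: bound} for every eligible central.
    """
    rows = sorted(gene_probes, key=lambda r: r[1])
    out = {}
    for j in range(1, len(rows) - 1):
        left, center, right = rows[j - 1], rows[j], rows[j + 1]
        if right[1] - left[1] > window:
            continue
        zs = [stats.norm.ppf(1.0 - min(max(r[2], 1e-300), 1.0)) for r in (left, center, right)]
        p_x_bar = 1.0 - stats.norm.cdf(sum(zs) / math.sqrt(3.0))
        clause1 = center[2] < strict and (left[2] < strict or right[2] < strict)
        clause2 = left[2] < relax or right[2] < relax
        out[center[0]] = (p_x_bar < alpha_central) and (clause1 or clause2)
    return out


def null_gene_bound_rate(n_probes=38, bins=300, alpha_central=0.05,
                         strict=0.05, relax=0.10):
    """P(>= 1 bound triple in a gene) for i.i.d. uniform probe p-values,
    by transfer-matrix numerical integration over equal-probability bins
    of the probit-transformed probe values."""
    q = (np.arange(bins) + 0.5) / bins
    z = stats.norm.ppf(q)
    p = 1.0 - q
    z_crit = stats.norm.isf(alpha_central) * math.sqrt(3.0)
    s = p < strict
    r = p < relax
    f = np.full((bins, bins), 1.0 / (bins * bins))
    for _ in range(n_probes - 2):
        fnew = np.empty((bins, bins))
        for k in range(bins):
            zsum = z[:, None] + z[None, :] + z[k]
            clause = r[:, None] | r[k] | (s[None, :] & (s[:, None] | s[k]))
            bound = (zsum > z_crit) & clause
            fnew[:, k] = ((~bound) * f).sum(axis=0) / bins
        f = fnew
    return 1.0 - float(f.sum())


def kappa_2x2_identity(a, b, c, d):
    """kappa = 2(ad - bc) / [(a+b)(b+d) + (a+c)(c+d)]."""
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    return 2.0 * (a * d - b * c) / denom if denom else float("nan")


def pooled_two_sample_t(x, y):
    """Classic pooled-variance two-sample t and two-sided p, per gene row."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.shape[1], y.shape[1]
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / df
    t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def two_sample_z_power(effect, n1, n2, alpha=0.05):
    """Power of a two-sided two-sample z-test at the given standardized
    mean difference."""
    se = math.sqrt(1.0 / n1 + 1.0 / n2)
    crit = stats.norm.isf(alpha / 2.0)
    return float(
        stats.norm.sf(crit - effect / se) + stats.norm.cdf(-crit - effect / se)
    )


def binom_bounds_99(p, n):
    """Normal-approximation 99% bounds on a proportion estimate."""
    half = 2.5758 * math.sqrt(p * (1 - p) / n)
    return p - half, p + half
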