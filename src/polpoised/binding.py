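"""Promoter-binding calls from tiling-array probe data.

Implements the probe-triple neighborhood rule for calling bound sites,
gene-level p-value combination (Fisher joint and geometric-average
transforms), tight/loose/unbound classification, and the stalling index
contrasting TSS-proximal and downstream enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ["probe_id", "gene_id", "offset_nt", "log_ratio"]

#: scale factor making the MAD a consistent estimator of a normal sigma
MAD_TO_SD = 1.4826


class DegenerateArrayError(ValueError):
    """Raised when an array's probe log-ratios have zero spread (MAD = 0)."""


@dataclass(frozen=True)
class BindingConfig:
    """Thresholds and windows of the binding caller.

    ``alpha_central`` applies to the composite triple p-value; the two
    neighbor thresholds implement the two admission clauses of the
    neighborhood rule. ``triple_window_nt`` bounds the span of an
    eligible probe triple (outermost probe centers).
    """

    alpha_central: float = 0.05
    alpha_neighbor_strict: float = 0.05
    alpha_neighbor_relaxed: float = 0.10
    triple_window_nt: int = 1100
    si_proximal_window: tuple[int, int] = (-300, 300)
    si_distal_window: tuple[int, int] = (300, 2500)
    tight_alpha: float = 0.05
    loose_alpha: float = 0.13
    pseudo_floor: float = 1e-300
    si_linear_scale: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha_central <= self.alpha_neighbor_relaxed < 1):
            raise ValueError(
                "require 0 < alpha_central <= alpha_neighbor_relaxed < 1"
            )
        if self.triple_window_nt <= 0:
            raise ValueError("triple_window_nt must be positive")
        for lo, hi in (self.si_proximal_window, self.si_distal_window):
            if lo >= hi:
                raise ValueError("SI windows must be non-degenerate (lo < hi)")
        if not (0 < self.tight_alpha < self.loose_alpha < 1):
            raise ValueError("require 0 < tight_alpha < loose_alpha < 1")
        if self.pseudo_floor <= 0:
            raise ValueError("pseudo_floor must be positive")


def _validate_pvals(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def probe_pvalues(probes: pd.DataFrame) -> pd.DataFrame:
    """Fill ``p_probe`` as the upper-tail probability of the robustly
    standardized log-ratio.

    Center is the array median, scale is 1.4826 x MAD across the whole
    array (all genes together). Stands in for the vendor error model.
    """
    if "log_ratio" not in probes.columns:
        raise ValueError("probe table must have a log_ratio column")
    x = probes["log_ratio"].to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateArrayError("array MAD is zero; cannot standardize")
    out = probes.copy()
    # floor guards against underflow to exactly 0 for extreme enrichment
    out["p_probe"] = np.clip(
        stats.norm.sf((x - med) / (MAD_TO_SD * mad)), 1e-300, 1.0
    )
    return out


def composite_triple_p(p_left, p_center, p_right, *, floor: float = 1e-300):
    """Equal-weight Stouffer combination of a probe triple.

    Each p is probit-transformed to an upper-tail z, the mean z (scaled
    by sqrt(3)) is referred back to the normal upper tail. Symmetric in
    its three arguments; accepts scalars or aligned arrays.
    """
    ps = [np.asarray(p, dtype=float) for p in (p_left, p_center, p_right)]
    for p in ps:
        if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
            raise ValueError("p-values must lie in (0, 1]")
    z = sum(stats.norm.isf(np.clip(p, floor, 1.0)) for p in ps)
    out = stats.norm.sf(z / math.sqrt(3.0))
    if all(np.isscalar(p) or np.ndim(p) == 0 for p in (p_left, p_center, p_right)):
        return float(out)
    return out


def fisher_joint_p(site_pvals) -> float:
    """Fisher's method: -2 sum(ln p) referred to chi-square with 2n df."""
    p = _validate_pvals(site_pvals)
    statistic = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(statistic, 2 * p.size))


def geometric_average_p(site_pvals) -> float:
    """Chi-square(2 df) transform of the geometric-mean p-value.

    Because the chi-square(2) survival function is exp(-x/2), the result
    equals the geometric mean itself; the transform is kept explicit so
    the construction mirrors the joint statistic.
    """
    p = _validate_pvals(site_pvals)
    g = float(np.exp(np.mean(np.log(p))))
    statistic = -2.0 * math.log(g)
    return float(stats.chi2.sf(statistic, 2))


def call_sites(probes: pd.DataFrame, config: BindingConfig | None = None) -> pd.DataFrame:
    """Apply the triple neighborhood rule to the probes of one or more genes.

    For every eligible central probe (one neighbor on each side within the
    same gene, outermost probes within ``triple_window_nt``) the composite
    triple p-value ``p_x_bar`` is computed, and the site is bound iff
    ``p_x_bar < alpha_central`` and either (1) the central probe and at
    least one neighbor are below the strict neighbor threshold, or (2) a
    neighbor is below the relaxed threshold.

    Returns one row per eligible central probe with columns
    gene_id, central_probe_id, offset_nt, p_x_bar, bound.
    """
    config = config or BindingConfig()
    if "p_probe" not in probes.columns:
        raise ValueError("p_probe missing; run probe_pvalues first")
    frames = []
    for gene_id, grp in probes.groupby("gene_id", sort=True):
        grp = grp.sort_values("offset_nt", kind="mergesort")
        n = len(grp)
        if n < 3:
            continue
        off = grp["offset_nt"].to_numpy()
        p = grp["p_probe"].to_numpy(dtype=float)
        span_ok = (off[2:] - off[:-2]) <= config.triple_window_nt
        if not span_ok.any():
            continue
        pl, pc, pr = p[:-2], p[1:-1], p[2:]
        p_x_bar = composite_triple_p(pl, pc, pr, floor=config.pseudo_floor)
        p_min_nb = np.minimum(pl, pr)
        clause1 = (pc < config.alpha_neighbor_strict) & (
            p_min_nb < config.alpha_neighbor_strict
        )
        clause2 = p_min_nb < config.alpha_neighbor_relaxed
        bound = (p_x_bar < config.alpha_central) & (clause1 | clause2)
        keep = span_ok
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "central_probe_id": grp["probe_id"].to_numpy()[1:-1][keep],
                    "offset_nt": off[1:-1][keep],
                    "p_x_bar": np.asarray(p_x_bar)[keep],
                    "bound": bound[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "central_probe_id", "offset_nt", "p_x_bar", "bound"]
        )
    return pd.concat(frames, ignore_index=True)


def classify_binder(p_gav: float, n_sites: int, config: BindingConfig | None = None) -> str:
    """Tight / loose / unbound classification from the gene-level p_gav.

    A gene with no bound site is unbound regardless of p_gav.
    """
    config = config or BindingConfig()
    if n_sites == 0 or not np.isfinite(p_gav):
        return "unbound"
    if p_gav < config.tight_alpha:
        return "tight"
    if p_gav < config.loose_alpha:
        return "loose"
    return "unbound"


def stalling_index(gene_probes: pd.DataFrame, config: BindingConfig | None = None) -> float:
    """Ratio of peak TSS-proximal enrichment to mean downstream enrichment.

    Enrichment is taken on the linear scale (2**log_ratio) by default.
    Returns NaN (logged) when either window holds no probe.
    """
    config = config or BindingConfig()
    off = gene_probes["offset_nt"].to_numpy()
    lr = gene_probes["log_ratio"].to_numpy(dtype=float)
    lo, hi = config.si_proximal_window
    prox = lr[(off >= lo) & (off <= hi)]
    dlo, dhi = config.si_distal_window
    dist = lr[(off > dlo) & (off <= dhi)]
    if prox.size == 0 or dist.size == 0:
        logger.warning("stalling index undefined: empty proximal or distal window")
        return float("nan")
    if config.si_linear_scale:
        return float(np.max(2.0 ** prox) / np.mean(2.0 ** dist))
    return float(np.max(prox) / np.mean(dist))


def summarize_genes(
    probes: pd.DataFrame, config: BindingConfig | None = None
) -> pd.DataFrame:
    """Per-gene binding summary over a probe table.

    ``n_sites`` counts bound sites. ``p_jt``/``p_gav`` combine the
    composite triple p-values of *all* eligible triples in the gene's
    window, so that genes whose evidence is diffuse can land in the
    loose class (a combination restricted to already-significant sites
    could never exceed the tight threshold).

    Returns a DataFrame indexed by gene_id with columns n_sites, p_jt,
    p_gav, binder_class, stalling_index, bound.
    """
    config = config or BindingConfig()
    if "p_probe" not in probes.columns:
        probes = probe_pvalues(probes)
    sites = call_sites(probes, config)
    sites_by_gene = dict(tuple(sites.groupby("gene_id", sort=False))) if len(sites) else {}
    empty = sites.iloc[0:0]
    records = []
    for gene_id, grp in probes.groupby("gene_id", sort=True):
        gsites = sites_by_gene.get(gene_id, empty)
        n_bound = int(gsites["bound"].sum())
        if len(gsites):
            all_p = np.clip(gsites["p_x_bar"].to_numpy(), config.pseudo_floor, 1.0)
            p_jt = fisher_joint_p(all_p)
            p_gav = geometric_average_p(all_p)
        else:
            p_jt = float("nan")
            p_gav = float("nan")
        binder_class = classify_binder(p_gav, n_bound, config)
        records.append(
            {
                "gene_id": gene_id,
                "n_sites": n_bound,
                "p_jt": p_jt,
                "p_gav": p_gav,
                "binder_class": binder_class,
                "stalling_index": stalling_index(grp, config),
            }
        )
    out = pd.DataFrame.from_records(records).set_index("gene_id")
    out["bound"] = out["binder_class"].isin(["tight", "loose"])
    return out
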