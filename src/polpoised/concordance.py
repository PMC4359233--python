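"""Directional agreement between two differential-expression analyses.

Cohen's kappa on the 2x2 up/down table of overlapping significant genes,
a random-gene permutation null for kappa, and a resampling test for the
size of the overlap between two gene lists drawn from two universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DirectionTable:
    """2x2 direction contingency: a both-up, b up/down, c down/up, d both-down."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_same(self) -> int:
        return self.a + self.d

    @property
    def n_opposite(self) -> int:
        return self.b + self.c

    def percent_same_direction(self) -> float:
        return 100.0 * self.n_same / self.n


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se0: float        # null-hypothesis large-sample SE
    se1: float        # alternative-hypothesis SE
    z: float
    p: float
    po: float
    pe: float
    table: DirectionTable

    @property
    def se(self) -> float:
        return self.se0


@dataclass(frozen=True)
class OverlapTestResult:
    observed_overlap: int
    null_mean: float
    null_sd: float
    p_empirical: float
    p_ratio: float    # mean random overlap / observed (legacy ratio estimator)
    rounds: int
    seed: int


def direction_table(de_a: pd.DataFrame, de_b: pd.DataFrame) -> DirectionTable:
    """Cross-tabulate up/down directions over the overlap of the
    significant genes of two DE tables; 'zero' directions are dropped."""
    sig_a = de_a[(de_a["significant"]) & (de_a["direction"] != "zero")]
    sig_b = de_b[(de_b["significant"]) & (de_b["direction"] != "zero")]
    common = sig_a.index.intersection(sig_b.index)
    if len(common) == 0:
        raise ValueError("no overlapping significant genes")
    da = sig_a.loc[common, "direction"]
    db = sig_b.loc[common, "direction"]
    return DirectionTable(
        a=int(((da == "up") & (db == "up")).sum()),
        b=int(((da == "up") & (db == "down")).sum()),
        c=int(((da == "down") & (db == "up")).sum()),
        d=int(((da == "down") & (db == "down")).sum()),
    )


def cohens_kappa(table: DirectionTable) -> KappaResult:
    """Chance-corrected agreement with both the null-hypothesis SE used
    for the z-test and the alternative-hypothesis (Fleiss) SE.

    Returns NaN kappa when the marginals are degenerate (pe = 1).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    p = np.array([[a, b], [c, d]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = p[0, 0] + p[1, 1]
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        return KappaResult(
            kappa=float("nan"), se0=float("nan"), se1=float("nan"),
            z=float("nan"), p=float("nan"), po=po, pe=pe, table=table,
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-style SE under H0: kappa = 0
    s = float(sum(row[i] * col[i] * (row[i] + col[i]) for i in range(2)))
    se0 = np.sqrt(max(pe + pe**2 - s, 0.0)) / ((1.0 - pe) * np.sqrt(n))

    # large-sample SE under the alternative
    t1 = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in range(2)
    )
    t2 = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    t3 = (kappa - pe * (1.0 - kappa)) ** 2
    se1 = np.sqrt(max(t1 + t2 - t3, 0.0)) / ((1.0 - pe) * np.sqrt(n))

    z = kappa / se0 if se0 > 0 else float("nan")
    pval = float(stats.norm.sf(z)) if np.isfinite(z) else float("nan")
    return KappaResult(kappa=float(kappa), se0=float(se0), se1=float(se1),
                       z=float(z), p=pval, po=float(po), pe=pe, table=table)


def kappa_identity(table: DirectionTable) -> float:
    """Closed-form 2x2 identity: kappa = 2(ad-bc)/[(a+b)(b+d)+(a+c)(c+d)]."""
    a, b, c, d = table.a, table.b, table.c, table.d
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return float("nan")
    return 2.0 * (a * d - b * c) / denom


@dataclass
class KappaNullResult:
    values: np.ndarray
    missing_rounds: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values)) if len(self.values) else float("nan")

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1)) if len(self.values) > 1 else float("nan")


def kappa_permutation_null(
    universe_a,
    de_b_directions: pd.Series,
    n_draw: int,
    rounds: int = 1000,
    seed: int = 0,
    *,
    direction_source: str = "coin",
) -> KappaNullResult:
    """Null distribution of kappa for random gene draws.

    Each round draws ``n_draw`` genes from ``universe_a`` without
    replacement, assigns directions on side A (fair coin, or a permutation
    of the observed B directions when ``direction_source='permute'``),
    intersects with the B table's genes, and computes kappa. Rounds whose
    overlap is empty or degenerate are recorded as NaN, not dropped.
    """
    universe_a = np.asarray(list(universe_a))
    if n_draw > universe_a.size:
        raise ValueError("n_draw exceeds the universe size")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    de_b_directions = de_b_directions[de_b_directions != "zero"]
    b_genes = de_b_directions.index
    rng = np.random.default_rng(seed)
    values = np.full(rounds, np.nan)
    missing = 0
    for r in range(rounds):
        drawn = rng.choice(universe_a, size=n_draw, replace=False)
        if direction_source == "coin":
            dirs = np.where(rng.random(n_draw) < 0.5, "up", "down")
        elif direction_source == "permute":
            pool = de_b_directions.to_numpy()
            dirs = rng.choice(pool, size=n_draw, replace=True)
        else:
            raise ValueError("direction_source must be 'coin' or 'permute'")
        da = pd.Series(dirs, index=drawn)
        common = b_genes.intersection(da.index)
        if len(common) == 0:
            missing += 1
            continue
        dav = da.loc[common].to_numpy()
        dbv = de_b_directions.loc[common].to_numpy()
        table = DirectionTable(
            a=int(((dav == "up") & (dbv == "up")).sum()),
            b=int(((dav == "up") & (dbv == "down")).sum()),
            c=int(((dav == "down") & (dbv == "up")).sum()),
            d=int(((dav == "down") & (dbv == "down")).sum()),
        )
        values[r] = cohens_kappa(table).kappa
    return KappaNullResult(values=values, missing_rounds=missing, seed=seed)


def expected_overlap(size_a: int, size_b: int, universe_a, universe_b) -> float:
    """Closed-form expected overlap of independent uniform draws:
    sum over shared genes of (size_a/|Ua|) * (size_b/|Ub|)."""
    ua, ub = set(universe_a), set(universe_b)
    shared = len(ua & ub)
    return shared * (size_a / len(ua)) * (size_b / len(ub))


def overlap_resampling_test(
    list_a,
    universe_a,
    list_b,
    universe_b,
    rounds: int = 10_000,
    seed: int = 0,
) -> OverlapTestResult:
    """Resampling null for the overlap of two gene lists.

    Each round draws |list_a| genes from universe_a and |list_b| from
    universe_b and counts the intersection. p_empirical uses the add-one
    rule; p_ratio is the legacy mean-random-over-observed estimator.
    """
    set_a, set_b = set(list_a), set(list_b)
    ua = np.asarray(sorted(set(universe_a)))
    ub = np.asarray(sorted(set(universe_b)))
    if not set_a <= set(ua) or not set_b <= set(ub):
        raise ValueError("lists must be subsets of their universes")
    observed = len(set_a & set_b)
    if observed > 0 and len(set(ua) & set(ub)) == 0:
        raise ValueError("disjoint universes cannot produce a non-zero overlap")
    rng = np.random.default_rng(seed)
    ka, kb = len(set_a), len(set_b)
    counts = np.empty(rounds, dtype=int)
    shared = set(ua) & set(ub)
    for r in range(rounds):
        da = rng.choice(ua, size=ka, replace=False)
        db = rng.choice(ub, size=kb, replace=False)
        counts[r] = len(set(da) & set(db)) if shared else 0
    null_mean = float(counts.mean())
    p_emp = float((1 + np.sum(counts >= observed)) / (rounds + 1))
    p_ratio = float(null_mean / observed) if observed > 0 else float("inf")
    return OverlapTestResult(
        observed_overlap=observed,
        null_mean=null_mean,
        null_sd=float(counts.std(ddof=1)),
        p_empirical=p_emp,
        p_ratio=p_ratio,
        rounds=rounds,
        seed=seed,
    )
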