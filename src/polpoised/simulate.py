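"""Synthetic promoter-tiling and expression data with planted ground truth.

Emulates a promoter tiling array (probes ~200 nt apart over -5000..+2500
around each TSS), replicated two-group cell-line expression, and several
independently scaled tumor cohorts carrying a continuous marker-gene
gradient. Every planted class (bound, regulated, poised, tissue-dependent,
stalled) is recorded so downstream calls can be scored.

The probe-level noise model (i.i.d. Gaussian in log-ratio space, Gaussian
peak for stalled genes, uniform elevation for elongating genes) is a
stand-in: no probe-level signal distribution is dictated by the assay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

MARKER_GENE = "HER2"

DEFAULT_CELL_LINES = (
    ("MCF7HER2", "+", 5),
    ("BT474", "+", 5),
    ("MDA453", "+", 5),
    ("MCF7", "-", 5),
)


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 200
    probe_spacing: int = 200
    promoter_window: tuple[int, int] = (-5000, 2500)
    cell_lines: tuple[tuple[str, str, int], ...] = DEFAULT_CELL_LINES
    n_cohorts: int = 5
    cohort_sizes: tuple[int, ...] = (60, 60, 60, 60, 60)
    fraction_bound_in_her2pos: float = 0.2
    fraction_regulated_of_bound: float = 0.3
    fraction_poised_expressed_in_tumor: float = 0.4
    fraction_stalled_of_bound: float = 0.5
    peak_height: float = 2.5
    peak_width: float = 500.0
    noise_sd: float = 0.3
    effect_size_de: float = 3.0
    expr_noise_sd: float = 0.5
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.promoter_window
        if lo >= hi:
            raise ValueError("promoter_window must be (lo, hi) with lo < hi")
        for frac in (
            self.fraction_bound_in_her2pos,
            self.fraction_regulated_of_bound,
            self.fraction_poised_expressed_in_tumor,
            self.fraction_stalled_of_bound,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ValueError("cohort_sizes length must equal n_cohorts")
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        for name, status, reps in self.cell_lines:
            if status not in "+-":
                raise ValueError(f"line {name}: status must be '+' or '-'")
            if reps < 2:
                raise ValueError(f"line {name}: need >= 2 expression replicates")
        if not any(st == "+" for _, st, _ in self.cell_lines) or not any(
            st == "-" for _, st, _ in self.cell_lines
        ):
            raise ValueError("need at least one '+' line and one '-' line")

    @property
    def probe_offsets(self) -> np.ndarray:
        lo, hi = self.promoter_window
        return np.arange(lo, hi + 1, self.probe_spacing)

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    bound_genes_per_line: dict[str, set]
    regulated_genes: dict[str, str]       # gene -> direction
    poised_genes: set
    tissue_dependent_genes: dict[str, str]
    stalled_genes: set

    def validate(self, her2_status: dict[str, str] | None = None) -> None:
        assert set(self.regulated_genes) & self.poised_genes == set()
        assert set(self.tissue_dependent_genes) <= self.poised_genes
        if her2_status:
            for line, status in her2_status.items():
                if status == "+":
                    assert self.poised_genes <= self.bound_genes_per_line[line]

    def to_json(self, path) -> None:
        payload = {
            "bound_genes_per_line": {
                k: sorted(v) for k, v in self.bound_genes_per_line.items()
            },
            "regulated_genes": dict(sorted(self.regulated_genes.items())),
            "poised_genes": sorted(self.poised_genes),
            "tissue_dependent_genes": dict(sorted(self.tissue_dependent_genes.items())),
            "stalled_genes": sorted(self.stalled_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            bound_genes_per_line={k: set(v) for k, v in d["bound_genes_per_line"].items()},
            regulated_genes=d["regulated_genes"],
            poised_genes=set(d["poised_genes"]),
            tissue_dependent_genes=d["tissue_dependent_genes"],
            stalled_genes=set(d["stalled_genes"]),
        )


def _plant_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    genes = np.array(config.gene_ids)
    n_bound = int(round(config.fraction_bound_in_her2pos * config.n_genes))
    bound = rng.choice(genes, size=n_bound, replace=False)
    n_reg = int(round(config.fraction_regulated_of_bound * n_bound))
    regulated = rng.choice(bound, size=n_reg, replace=False)
    reg_dirs = {
        g: ("up" if u < 0.5 else "down") for g, u in zip(regulated, rng.random(n_reg))
    }
    poised = set(bound) - set(regulated)
    n_td = int(round(config.fraction_poised_expressed_in_tumor * len(poised)))
    td = rng.choice(sorted(poised), size=n_td, replace=False)
    td_dirs = {g: ("up" if u < 0.5 else "down") for g, u in zip(td, rng.random(n_td))}
    n_stalled = int(round(config.fraction_stalled_of_bound * n_bound))
    stalled = set(rng.choice(bound, size=n_stalled, replace=False))
    bound_per_line = {
        name: (set(bound) if status == "+" else set())
        for name, status, _ in config.cell_lines
    }
    truth = GroundTruth(
        bound_genes_per_line=bound_per_line,
        regulated_genes=reg_dirs,
        poised_genes=poised,
        tissue_dependent_genes=td_dirs,
        stalled_genes=stalled,
    )
    truth.validate({name: status for name, status, _ in config.cell_lines})
    return truth


def simulate_chipchip(config: SimConfig):
    """Per-line probe tables plus the planted ground truth.

    Bound genes in positive lines carry either a Gaussian log-ratio peak
    centered at the TSS (stalled genes) or a uniform elevation at half the
    peak height across the window (elongating genes); everything else is
    i.i.d. Gaussian noise. Control lines carry noise only.

    Returns (dict line -> probe DataFrame, GroundTruth).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    truth = _plant_truth(config, np.random.default_rng(seeds[0]))
    rng = np.random.default_rng(seeds[1])

    offsets = config.probe_offsets
    genes = config.gene_ids
    n_probes = offsets.size
    gauss = config.peak_height * np.exp(-(offsets.astype(float) ** 2) / (2 * config.peak_width**2))
    flat = np.full(n_probes, config.peak_height / 2.0)

    gene_col = np.repeat(genes, n_probes)
    offset_col = np.tile(offsets, len(genes))
    probe_ids = np.array(
        [f"{g}:{o:+d}" for g, o in zip(gene_col, offset_col)]
    )

    tables = {}
    for name, status, _ in config.cell_lines:
        signal = np.zeros(len(genes) * n_probes)
        if status == "+":
            for i, g in enumerate(genes):
                if g in truth.bound_genes_per_line[name]:
                    shape = gauss if g in truth.stalled_genes else flat
                    signal[i * n_probes : (i + 1) * n_probes] = shape
        noise = rng.normal(0.0, config.noise_sd, size=signal.size) if config.noise_sd > 0 else 0.0
        tables[name] = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene_id": gene_col,
                "offset_nt": offset_col,
                "log_ratio": signal + noise,
            }
        )
    return tables, truth


def simulate_expression(config: SimConfig, truth: GroundTruth):
    """Replicated cell-line matrices and tumor cohort matrices.

    Cell lines: regulated genes differ between positive and control lines
    by ``effect_size_de`` (times the residual sd) in the planted
    direction; poised genes show no group difference; the marker gene is
    elevated in positive lines.

    Cohorts: each sample gets a latent standard-normal marker score; the
    marker gene row tracks it, tissue-dependent (and regulated) genes
    shift with it in their planted direction. Each cohort applies its own
    per-gene affine transform so per-cohort standardization is
    consequential.

    Returns (dict line -> ExpressionMatrix, dict cohort -> ExpressionMatrix).
    """
    seeds = np.random.SeedSequence((config.seed, 1)).spawn(2 + config.n_cohorts)
    genes = config.gene_ids + [MARKER_GENE]
    n_genes = len(genes)
    base_rng = np.random.default_rng(seeds[0])
    baseline = base_rng.normal(config.baseline_mean, 1.0, size=n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    line_rng = np.random.default_rng(seeds[1])
    sigma = config.expr_noise_sd
    line_matrices = {}
    for name, status, reps in config.cell_lines:
        mu = baseline.copy()
        if status == "+":
            mu[gene_index[MARKER_GENE]] += 5.0
            for g, d in truth.regulated_genes.items():
                mu[gene_index[g]] += (1 if d == "up" else -1) * config.effect_size_de * sigma
        vals = mu[:, None] + line_rng.normal(0.0, sigma, size=(n_genes, reps))
        cols = [f"{name}_r{i+1}" for i in range(reps)]
        df = pd.DataFrame(vals, index=genes, columns=cols)
        line_matrices[name] = ExpressionMatrix(df, pd.Series(name, index=cols))

    cohort_matrices = {}
    beta = config.effect_size_de
    for c, size in enumerate(config.cohort_sizes):
        rng = np.random.default_rng(seeds[2 + c])
        her2_score = rng.standard_normal(size)
        vals = baseline[:, None] + rng.normal(0.0, 1.0, size=(n_genes, size))
        vals[gene_index[MARKER_GENE]] = her2_score + rng.normal(0.0, 0.1, size=size)
        planted = dict(truth.tissue_dependent_genes)
        planted.update(truth.regulated_genes)
        for g, d in planted.items():
            vals[gene_index[g]] += (1 if d == "up" else -1) * beta * her2_score
        # cohort-specific per-gene affine distortion (scale, shift)
        scale = rng.uniform(0.5, 2.0, size=n_genes)
        shift = rng.normal(0.0, 2.0, size=n_genes)
        vals = vals * scale[:, None] + shift[:, None]
        name = f"cohort{c+1}"
        cols = [f"{name}_s{i+1}" for i in range(size)]
        df = pd.DataFrame(vals, index=genes, columns=cols)
        cohort_matrices[name] = ExpressionMatrix(df, pd.Series(name, index=cols))
    return line_matrices, cohort_matrices


def write_probe_tables(tables: dict[str, pd.DataFrame], outdir) -> None:
    import os

    for name, df in tables.items():
        df.to_csv(os.path.join(outdir, f"probes_{name}.tsv"), sep="\t", index=False)


def write_promoter_annotation(config: SimConfig, path) -> None:
    """BED-like promoter windows relative to each TSS."""
    lo, hi = config.promoter_window
    with open(path, "w") as fh:
        fh.write("gene_id\twindow_start\twindow_end\n")
        for g in config.gene_ids:
            fh.write(f"{g}\t{lo}\t{hi}\n")
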