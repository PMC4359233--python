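"""End-to-end pipeline: simulate -> binding calls -> DE -> concordance ->
classification cascade, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io
from .binding import BindingConfig, probe_pvalues, summarize_genes, call_sites
from .concordance import cohens_kappa, direction_table
from .expression import (
    DEConfig,
    ExpressionMatrix,
    merge_cohorts,
    moderated_t,
    quantile_normalize,
    standardize_genes,
    stratify_by_gene,
)
from .regulon import build_regulon, classify_cascade, recovery_metrics
from .simulate import (
    MARKER_GENE,
    GroundTruth,
    SimConfig,
    simulate_chipchip,
    simulate_expression,
    write_probe_tables,
    write_promoter_annotation,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    binding: BindingConfig = field(default_factory=BindingConfig)
    de: DEConfig = field(default_factory=DEConfig)
    marker_gene: str = MARKER_GENE
    require_all_comparisons: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            sim=SimConfig(**d.get("sim", {})),
            binding=BindingConfig(**d.get("binding", {})),
            de=DEConfig(**d.get("de", {})),
            marker_gene=d.get("marker_gene", MARKER_GENE),
            require_all_comparisons=d.get("require_all_comparisons", False),
            seed=d.get("seed", 0),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "sim": asdict(self.sim),
                "binding": asdict(self.binding),
                "de": asdict(self.de),
                "marker_gene": self.marker_gene,
                "require_all_comparisons": self.require_all_comparisons,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def tumor_de(
    cohorts: dict[str, ExpressionMatrix],
    marker_gene: str = MARKER_GENE,
    de_config: DEConfig | None = None,
) -> pd.DataFrame:
    """Standardize each cohort per gene, merge on the common gene set,
    stratify by the marker gene's expression, and test the strata."""
    de_config = de_config or DEConfig()
    standardized = [standardize_genes(m) for m in cohorts.values()]
    merged = merge_cohorts(standardized)
    pos, neg = stratify_by_gene(merged, marker_gene, de_config.stratify_quantile)
    sub = merged.values.loc[:, list(pos) + list(neg)]
    labels = pd.Series(
        ["pos"] * len(pos) + ["neg"] * len(neg), index=sub.columns
    )
    table = moderated_t(sub, labels, de_config, group_pos="pos", group_neg="neg")
    return table.drop(index=marker_gene.upper(), errors="ignore")


def cellline_de(
    lines: dict[str, ExpressionMatrix],
    her2_status: dict[str, str],
    de_config: DEConfig | None = None,
    *,
    normalize: bool = True,
) -> dict[str, pd.DataFrame]:
    """One DE table per positive line vs the pooled control line(s)."""
    de_config = de_config or DEConfig()
    controls = [ln for ln, st in her2_status.items() if st == "-"]
    positives = [ln for ln, st in her2_status.items() if st == "+"]
    if not controls or not positives:
        raise ValueError("need at least one positive and one control line")
    out = {}
    for ln in positives:
        mats = [lines[ln]] + [lines[c] for c in controls]
        values = pd.concat([m.values for m in mats], axis=1)
        if normalize:
            values = quantile_normalize(values)
        labels = pd.concat([m.labels for m in mats])
        labels = labels.where(labels == ln, "control")
        table = moderated_t(values, labels, de_config, group_pos=ln, group_neg="control")
        out[ln] = table.drop(index=MARKER_GENE, errors="ignore")
    return out


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run the full synthetic pipeline and write all artifacts to outdir.

    Returns the manifest dict (also written as manifest.json).
    """
    os.makedirs(outdir, exist_ok=True)
    her2_status = {name: status for name, status, _ in config.sim.cell_lines}

    probes, truth = simulate_chipchip(config.sim)
    line_mats, cohort_mats = simulate_expression(config.sim, truth)
    write_probe_tables(probes, outdir)
    write_promoter_annotation(config.sim, os.path.join(outdir, "promoters.tsv"))
    truth.to_json(os.path.join(outdir, "ground_truth.json"))
    for name, m in line_mats.items():
        m.to_tsv(os.path.join(outdir, f"expr_line_{name}.tsv"))
    for name, m in cohort_mats.items():
        m.to_tsv(os.path.join(outdir, f"expr_{name}.tsv"))

    summaries = {}
    for name, table in probes.items():
        with_p = probe_pvalues(table)
        sites = call_sites(with_p, config.binding)
        io.write_site_calls(sites, os.path.join(outdir, f"sites_{name}.tsv"))
        summary = summarize_genes(with_p, config.binding)
        io.write_binding_summary(summary, os.path.join(outdir, f"binding_{name}.tsv"))
        summaries[name] = summary
        logger.info("line %s: %d bound genes", name, int(summary["bound"].sum()))

    regulon = build_regulon(summaries, her2_status)

    cl_de = cellline_de(line_mats, her2_status, config.de)
    for name, table in cl_de.items():
        io.write_de_table(table, os.path.join(outdir, f"de_line_{name}.tsv"))
    t_de = tumor_de(cohort_mats, config.marker_gene, config.de)
    io.write_de_table(t_de, os.path.join(outdir, "de_tumor.tsv"))

    kappas = {}
    for name, table in cl_de.items():
        try:
            dt = direction_table(table, t_de)
            res = cohens_kappa(dt)
            kappas[name] = {
                "a": dt.a, "b": dt.b, "c": dt.c, "d": dt.d,
                "kappa": res.kappa, "se0": res.se0, "se1": res.se1,
                "z": res.z, "p": res.p,
                "percent_same_direction": dt.percent_same_direction(),
            }
        except ValueError:
            kappas[name] = {"error": "no overlapping significant genes"}
    io.write_json(kappas, os.path.join(outdir, "concordance.json"))

    cascade = classify_cascade(
        regulon, cl_de, t_de, require_all_comparisons=config.require_all_comparisons
    )
    io.write_gene_list(cascade.regulon, os.path.join(outdir, "class_regulon.txt"))
    io.write_gene_list(cascade.poised, os.path.join(outdir, "class_poised.txt"))
    pd.DataFrame(
        sorted(cascade.tissue_dependent.items()), columns=["gene_id", "direction"]
    ).to_csv(os.path.join(outdir, "class_tissue_dependent.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(cascade.concordant.items()), columns=["gene_id", "direction"]
    ).to_csv(os.path.join(outdir, "class_concordant.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "cascade_diagram.txt"), "w") as fh:
        fh.write(cascade.render_diagram() + "\n")

    universe = set(config.sim.gene_ids)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sim_seed": config.sim.seed,
        "class_sizes": cascade.summary(),
        "kappa": kappas,
        "recovery": {
            "regulon": recovery_metrics(
                cascade.regulon,
                set.intersection(
                    *(truth.bound_genes_per_line[ln] for ln, st in her2_status.items() if st == "+")
                ),
                universe,
            ),
            "poised": recovery_metrics(cascade.poised, truth.poised_genes, universe),
            "tissue_dependent": recovery_metrics(
                set(cascade.tissue_dependent),
                set(truth.tissue_dependent_genes),
                universe,
            ),
        },
    }
    io.write_json(manifest, os.path.join(outdir, "manifest.json"))
    summary_counts = cascade.summary()
    logger.info("cascade: %s", summary_counts)
    return manifest
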