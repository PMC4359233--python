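"""Set-algebra cascade classifying promoter-bound genes.

regulon      : bound in every high-expressing line, unbound in every control
regulated    : regulon genes differentially expressed in the line comparisons
concordant   : regulated genes moving the same direction in all comparisons
poised       : regulon minus concordant (bound but not consistently regulated)
tissue_dependent : poised genes differentially expressed in the tumor cohorts
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ClassificationCascade:
    regulon: set
    regulated: set
    concordant: dict            # gene -> direction
    concordant_partial: set
    poised: set
    tissue_dependent: dict      # gene -> direction
    not_assayed: set            # poised genes absent from the tumor universe

    @property
    def tissue_dependent_up(self) -> set:
        return {g for g, d in self.tissue_dependent.items() if d == "up"}

    @property
    def tissue_dependent_down(self) -> set:
        return {g for g, d in self.tissue_dependent.items() if d == "down"}

    def validate(self) -> None:
        """Assert the structural invariants of the cascade."""
        conc = set(self.concordant)
        assert conc <= self.regulated <= self.regulon
        assert self.poised == self.regulon - conc
        assert len(self.poised) + len(conc) == len(self.regulon)
        td = set(self.tissue_dependent)
        assert td <= self.poised
        assert self.tissue_dependent_up | self.tissue_dependent_down == td
        assert len(self.tissue_dependent_up) + len(self.tissue_dependent_down) == len(td)
        assert self.concordant_partial <= self.regulated - conc
        assert self.not_assayed <= self.poised

    def summary(self) -> dict:
        return {
            "regulon": len(self.regulon),
            "regulated": len(self.regulated),
            "concordant": len(self.concordant),
            "concordant_partial": len(self.concordant_partial),
            "poised": len(self.poised),
            "tissue_dependent": len(self.tissue_dependent),
            "tissue_dependent_up": len(self.tissue_dependent_up),
            "tissue_dependent_down": len(self.tissue_dependent_down),
            "not_assayed": len(self.not_assayed),
        }

    def render_diagram(self) -> str:
        """Count diagram of the cascade as indented text."""
        s = self.summary()
        lines = [
            f"regulon (bound in all high lines, not control) .... {s['regulon']}",
            f"|- regulated (DE in line comparisons) ............. {s['regulated']}",
            f"|  |- concordant (same direction, all lines) ...... {s['concordant']}",
            f"|  '- partial (same direction, all but one) ....... {s['concordant_partial']}",
            f"'- poised (regulon - concordant) .................. {s['poised']}",
            f"   |- tissue-dependent (tumor DE) ................. {s['tissue_dependent']}",
            f"   |  |- up ....................................... {s['tissue_dependent_up']}",
            f"   |  '- down ..................................... {s['tissue_dependent_down']}",
            f"   '- not assayed in tumors ....................... {s['not_assayed']}",
        ]
        return "\n".join(lines)


def build_regulon(
    binding_summaries: dict[str, pd.DataFrame],
    her2_status: dict[str, str],
) -> set:
    """Genes bound (tight or loose) in every positive line and unbound in
    every control line.

    ``binding_summaries`` maps line name to the per-gene summary table
    (indexed by gene_id, with a ``binder_class`` column). Lines with
    differing gene universes are restricted to the common universe.
    """
    pos = [ln for ln, st in her2_status.items() if st == "+"]
    neg = [ln for ln, st in her2_status.items() if st == "-"]
    if not pos or not neg:
        raise ValueError("need at least one positive and one control line")
    missing = set(pos + neg) - set(binding_summaries)
    if missing:
        raise ValueError(f"no binding summary for lines: {sorted(missing)}")

    universe = None
    for ln in pos + neg:
        idx = set(binding_summaries[ln].index)
        universe = idx if universe is None else universe & idx
    full = set().union(*(set(binding_summaries[ln].index) for ln in pos + neg))
    if len(universe) < len(full):
        logger.info(
            "gene universes differ across lines; restricted to %d common genes "
            "(%d dropped)", len(universe), len(full) - len(universe),
        )

    regulon = set()
    for g in universe:
        ok = all(
            binding_summaries[ln].loc[g, "binder_class"] in ("tight", "loose")
            for ln in pos
        ) and all(
            binding_summaries[ln].loc[g, "binder_class"] == "unbound" for ln in neg
        )
        if ok:
            regulon.add(g)
    return regulon


def classify_cascade(
    regulon: set,
    cellline_de: dict[str, pd.DataFrame],
    tumor_de: pd.DataFrame | None,
    *,
    require_all_comparisons: bool = False,
) -> ClassificationCascade:
    """Apply the cascade definitions given the regulon and DE tables.

    ``cellline_de`` maps comparison name to a DE table (indexed by
    gene_id with ``significant`` and ``direction`` columns). ``regulated``
    requires significance in at least one comparison by default, or in
    all of them with ``require_all_comparisons``. ``concordant`` always
    requires significance with a common direction in every comparison;
    ``concordant_partial`` relaxes that to all but one comparison.
    """
    comparisons = list(cellline_de)
    if not comparisons:
        raise ValueError("need at least one cell-line DE table")
    n_cmp = len(comparisons)

    regulated: set = set()
    concordant: dict = {}
    partial: set = set()
    for g in regulon:
        sig_dirs = []
        for name in comparisons:
            de = cellline_de[name]
            if g in de.index and de.loc[g, "significant"] and de.loc[g, "direction"] in ("up", "down"):
                sig_dirs.append(de.loc[g, "direction"])
        n_sig = len(sig_dirs)
        is_regulated = n_sig == n_cmp if require_all_comparisons else n_sig >= 1
        if not is_regulated:
            continue
        regulated.add(g)
        for d in ("up", "down"):
            votes = sum(1 for x in sig_dirs if x == d)
            if votes == n_cmp:
                concordant[g] = d
            elif votes == n_cmp - 1 and n_cmp >= 2:
                partial.add(g)
    partial -= set(concordant)

    poised = regulon - set(concordant)

    tissue_dependent: dict = {}
    not_assayed: set = set()
    if tumor_de is not None:
        tumor_genes = set(tumor_de.index)
        for g in poised:
            if g not in tumor_genes:
                not_assayed.add(g)
                continue
            if tumor_de.loc[g, "significant"] and tumor_de.loc[g, "direction"] in ("up", "down"):
                tissue_dependent[g] = tumor_de.loc[g, "direction"]
    else:
        not_assayed = set(poised)

    cascade = ClassificationCascade(
        regulon=set(regulon),
        regulated=regulated,
        concordant=concordant,
        concordant_partial=partial,
        poised=poised,
        tissue_dependent=tissue_dependent,
        not_assayed=not_assayed,
    )
    cascade.validate()
    return cascade


def recovery_metrics(predicted: set, truth: set, universe: set) -> dict:
    """Sensitivity / false-discovery / specificity of a predicted gene set."""
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe - predicted - truth)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "fdr": fp / len(predicted) if predicted else 0.0,
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }
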