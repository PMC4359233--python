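"""Flat-file readers and writers (TSV tables, gene lists, JSON results)."""

from __future__ import annotations

import json

import pandas as pd

PROBE_DTYPES = {"probe_id": str, "gene_id": str, "offset_nt": int, "log_ratio": float}


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    missing = {"probe_id", "gene_id", "offset_nt", "log_ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"probe table {path} missing columns: {sorted(missing)}")
    return df


def write_binding_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_binding_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_site_calls(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return df


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
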