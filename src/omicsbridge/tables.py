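"""Schema-validated TSV input/output for every pipeline table.

All tables are UTF-8 TSV with a header row, unquoted identifiers, and a
locale-independent decimal point.  Each named schema lists the required
columns with their kinds and the key columns that must be duplicate-free;
violations raise :class:`SchemaError` naming the column (and the first
offending line for type errors).  A write followed by a read returns an
equal table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """Raised when a table violates its declared schema."""


# column kinds: "str" | "int" | "float" | "bool"
SCHEMAS: dict[str, dict] = {
    "peptides": {
        "columns": {"protein_id": "str", "peptide_id": "str", "unique": "bool",
                    "score": "float", "i116": "float", "i117": "float",
                    "i119": "float", "i121": "float"},
        "key": ["protein_id", "peptide_id"],
    },
    "tags": {
        "columns": {"gene_id": "str", "W1R": "float", "W2R": "float",
                    "M1R": "float", "M2R": "float"},
        "key": ["gene_id"],
    },
    "mapping_summary": {
        "columns": {"library": "str", "raw": "int", "clean": "int",
                    "to_gene": "int", "to_genome": "int", "unknown": "int"},
        "key": ["library"],
    },
    "qpcr": {
        "columns": {"gene_id": "str", "group": "str", "replicate": "str",
                    "ct_target": "float", "ct_reference": "float"},
        "key": ["gene_id", "group", "replicate"],
    },
    "truth": {
        "columns": {"gene_id": "str", "is_de": "bool",
                    "true_log2fc_mrna": "float", "true_log2fc_protein": "float",
                    "base_log_abundance_mrna": "float",
                    "base_log_abundance_protein": "float",
                    "bio_log2fc_mrna": "float", "bio_log2fc_protein": "float"},
        "key": ["gene_id"],
    },
    "protein_quant": {
        "columns": {"protein_id": "str", "n_unique_peptides": "int",
                    "i116": "float", "i117": "float", "i119": "float",
                    "i121": "float", "ratio_rep1": "float", "ratio_rep2": "float",
                    "ratio_wt": "float", "ratio_mt": "float", "p_value": "float",
                    "p_flag": "str", "quantifiable": "bool", "normalized": "bool"},
        "key": ["protein_id"],
    },
    "dep_calls": {
        "columns": {"protein_id": "str", "ratio_rep1": "float",
                    "ratio_rep2": "float", "p_value": "float",
                    "n_unique_peptides": "int", "call": "str"},
        "key": ["protein_id"],
    },
    "threshold_report": {
        "columns": {"pairing": "str", "level": "float", "fold_change": "float"},
        "key": ["pairing", "level"],
    },
    "tpm": {
        "columns": {"gene_id": "str", "W1R": "float", "W2R": "float",
                    "M1R": "float", "M2R": "float"},
        "key": ["gene_id"],
    },
    "deg_results": {
        "columns": {"gene_id": "str", "M": "float", "D": "float",
                    "probability": "float", "call": "str"},
        "key": ["gene_id"],
    },
    "saturation": {
        "columns": {"library": "str", "depth": "int", "detected_genes": "int"},
        "key": ["library", "depth"],
    },
    "correlation_ladder": {
        "columns": {"level": "str", "n_pairs": "int", "r": "float",
                    "n_excluded": "int"},
        "key": ["level"],
    },
    "ladder_pairs": {
        "columns": {"gene_id": "str", "protein_log2_ratio": "float",
                    "mrna_log2_ratio": "float"},
        "key": ["gene_id"],
    },
    "overlap": {
        "columns": {"gene_id": "str"},
        "key": ["gene_id"],
    },
    "go_map": {
        "columns": {"gene_id": "str", "ontology": "str", "term": "str"},
        "key": ["gene_id", "ontology", "term"],
    },
    "go_tally": {
        "columns": {"ontology": "str", "term": "str", "count": "int",
                    "percent": "float"},
        "key": ["ontology", "term"],
    },
    "rq": {
        "columns": {"gene_id": "str", "delta_ct_wt": "float",
                    "delta_ct_mt": "float", "delta_delta_ct": "float",
                    "rq": "float"},
        "key": ["gene_id"],
    },
    "concordance": {
        "columns": {"gene_id": "str", "log2_rq": "float", "M": "float",
                    "concordant": "bool"},
        "key": ["gene_id"],
    },
}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _coerce(series: pd.Series, kind: str, column: str) -> pd.Series:
    if kind == "str":
        return series.astype(str)
    if kind == "bool":
        lowered = series.astype(str).str.lower()
        bad = ~lowered.isin(_BOOL_MAP)
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise SchemaError(f"column {column!r}: non-boolean value at line {line}")
        return lowered.map(_BOOL_MAP)
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna() & (series.astype(str).str.lower() != "nan")
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(f"column {column!r}: non-{kind} value at line {line}")
    if kind == "int":
        if not np.allclose(numeric.dropna() % 1, 0):
            raise SchemaError(f"column {column!r}: non-integer value")
        return numeric.astype("int64")
    return numeric.astype(float)


def validate_table(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Check columns, kinds, and key uniqueness; return the coerced table."""
    try:
        schema = SCHEMAS[schema_name]
    except KeyError:
        raise SchemaError(f"unknown schema {schema_name!r}") from None
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema_name!r}: missing column(s) {missing}")
    out = df.copy()
    for column, kind in schema["columns"].items():
        out[column] = _coerce(out[column], kind, column)
    key = schema["key"]
    duplicated = out.duplicated(subset=key)
    if duplicated.any():
        first = out.loc[duplicated, key].iloc[0].tolist()
        raise SchemaError(
            f"schema {schema_name!r}: duplicated key {key} value {first}")
    return out


def write_table(df: pd.DataFrame, path: str | Path,
                schema_name: str | None = None) -> Path:
    """Validate (when a schema is named) and write a TSV table."""
    if schema_name is not None:
        df = validate_table(df, schema_name)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and schema-validate a TSV table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    return validate_table(df, schema_name)
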