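"""Readers and writers for the pipeline's plain-text table formats.

All tables are TSV/CSV with header rows; gene identifiers are
case-sensitive strings.  Writers and readers round-trip exactly.  The
bioactivity CSV reader accepts ChEMBL-web-export-style dialects: quoted
fields and missing pChEMBL values as empty strings (read as absent, never
as zero).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import validate_counts


class IOFormatError(ValueError):
    pass


# -- count matrix -----------------------------------------------------------


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise IOFormatError(f"{path}: non-numeric counts ({exc})") from None
    return validate_counts(df)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


# -- sample metadata --------------------------------------------------------

_META_COLUMNS = ["sample_id", "group", "weeks_post_induction", "kw_bw", "treatment", "sex"]


def read_metadata_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise IOFormatError(f"{path}: metadata missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise IOFormatError(f"{path}: duplicate sample ids {dups[:5]}")
    if (df["kw_bw"].dropna() <= 0).any():
        raise IOFormatError(f"{path}: kw_bw must be positive where present")
    return df


def write_metadata_tsv(info: pd.DataFrame, path) -> None:
    info.to_csv(path, sep="\t", index=False)


# -- GMT pathway collections ------------------------------------------------


def read_gmt(path) -> dict[str, set]:
    """GMT: one pathway per line — name, description, then member genes."""
    pathways: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IOFormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in pathways:
                raise IOFormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
            pathways[name] = set(g for g in fields[2:] if g)
    return pathways


def write_gmt(pathways: dict[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# -- bioactivities ----------------------------------------------------------

_BIO_COLUMNS = ["compound_id", "target_id", "target_organism", "pchembl", "confidence_score", "assay_id"]


def read_bioactivities_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str, "target_id": str, "assay_id": str})
    rename = {"target_symbol": "target_id", "organism": "target_organism", "confidence": "confidence_score"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    missing = [c for c in _BIO_COLUMNS if c not in df.columns]
    if missing:
        raise IOFormatError(f"{path}: bioactivity table missing columns {missing}")
    df["pchembl"] = pd.to_numeric(df["pchembl"], errors="raise")  # empty -> NaN (absent)
    df["confidence_score"] = df["confidence_score"].astype(int)
    return df[_BIO_COLUMNS]


def write_bioactivities_csv(records: pd.DataFrame, path) -> None:
    records[_BIO_COLUMNS].to_csv(path, index=False)


# -- compound annotations ---------------------------------------------------


def read_compounds_csv(path) -> pd.DataFrame:
    """Compound table with ;-separated ATC codes and target:action MoA triples."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                atc = [c for c in (row.get("atc_codes") or "").split(";") if c]
                moa = []
                for entry in (row.get("moa") or "").split(";"):
                    if not entry:
                        continue
                    tgt, action = entry.split(":")
                    moa.append((tgt, action))
                rows.append(
                    {
                        "compound_id": row["compound_id"],
                        "name": row.get("name", row["compound_id"]),
                        "max_phase": int(row["max_phase"]) if row.get("max_phase") else 0,
                        "atc_codes": atc,
                        "moa": moa,
                    }
                )
            except (KeyError, ValueError) as exc:
                raise IOFormatError(f"{path}:{lineno}: malformed compound row ({exc})") from None
    df = pd.DataFrame(rows, columns=["compound_id", "name", "max_phase", "atc_codes", "moa"])
    if df["compound_id"].duplicated().any():
        dups = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise IOFormatError(f"{path}: duplicate compound ids {dups[:5]}")
    return df


def write_compounds_csv(compounds: pd.DataFrame, path) -> None:
    out = compounds.copy()
    out["atc_codes"] = out["atc_codes"].map(lambda xs: ";".join(xs))
    out["moa"] = out["moa"].map(lambda xs: ";".join(f"{t}:{a}" for t, a in xs))
    out.to_csv(path, index=False)


# -- ortholog map -----------------------------------------------------------


def read_orthologs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mouse_id", "human_symbol"):
        if col not in df.columns:
            raise IOFormatError(f"{path}: ortholog map missing column {col!r}")
    return df[["mouse_id", "human_symbol"]]


def write_orthologs_tsv(orthologs: pd.DataFrame, path) -> None:
    orthologs.to_csv(path, sep="\t", index=False)


# -- gene annotation tables -------------------------------------------------


def read_stage_genes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "stage", "direction"):
        if col not in df.columns:
            raise IOFormatError(f"{path}: stage gene table missing column {col!r}")
    return df


def write_stage_genes_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- JSON reports -----------------------------------------------------------


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
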