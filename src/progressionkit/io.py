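"""Tabular I/O: TSV tables, BED peaks, GMT gene sets, plain lists.

All tables are tab-separated with headers; BED is 0-based half-open;
beta matrices are CpG x sample with a metadata sidecar TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .methylation import BetaMatrix, ReferencePanel

COUNT_COLUMNS = ["patient_id", "site_id", "chrom", "pos", "ref_count_g",
                 "alt_count_g", "ref_count_t1", "alt_count_t1",
                 "ref_count_t2", "alt_count_t2"]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: failed to parse TSV ({exc})") from exc


def read_allele_counts(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns and c != "patient_id"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_segments(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    for col in ("chrom", "start", "end", "timepoint"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df


def read_beta_matrix(values_path, metadata_path) -> BetaMatrix:
    values = _read_tsv(values_path, index_col=0)
    metadata = _read_tsv(metadata_path, index_col="sample_id")
    return BetaMatrix(values, metadata)


def write_beta_matrix(bm: BetaMatrix, values_path, metadata_path) -> None:
    Path(values_path).parent.mkdir(parents=True, exist_ok=True)
    bm.values.to_csv(values_path, sep="\t", index_label="cpg_id")
    bm.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_reference_panel(path) -> ReferencePanel:
    return ReferencePanel(_read_tsv(path, index_col=0))


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str}, usecols=[0, 1, 2])
    df.columns = ["chrom", "start", "end"]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    for col in ("cpg_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT lines need >= 3 fields")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"{path}:{line_no}: empty gene set {parts[0]!r}")
            sets[parts[0]] = genes
    return sets


def read_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
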