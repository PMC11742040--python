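"""TSV/JSON file formats shared by the pipeline stages.

All tables are TSV, UTF-8, '.' decimal separator, 'NA' for missing values.
Gene identifiers are opaque strings. Counts tables have a header row of
sample identifiers and gene identifiers in the first column.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    pass


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples integer count table from TSV.

    Rejects duplicate gene or sample identifiers and non-integer or negative
    entries, naming the offending cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate sample columns {dup}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene identifiers {dup[:5]}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric)) | (numeric < 0)
        if bad.any():
            gene = bad.idxmax()
            line = df.index.get_loc(gene) + 2  # header + 1-based
            raise ParseError(
                f"{path}: non-negative integer expected at gene '{gene}', "
                f"sample '{col}' (line {line}): {df[col].loc[gene]!r}")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(mtx_path: str | Path, genes_path: str | Path,
                    samples_path: str | Path) -> pd.DataFrame:
    """Sparse MatrixMarket count import (genes x samples) with sidecar lists."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    if mat.shape != (len(genes), len(samples)):
        raise ParseError(f"{mtx_path}: matrix shape {mat.shape} does not match "
                         f"{len(genes)} genes x {len(samples)} samples")
    if np.any(mat < 0) or np.any(mat != np.floor(mat)):
        raise ParseError(f"{mtx_path}: counts must be non-negative integers")
    df = pd.DataFrame(mat.astype(np.int64), index=genes, columns=samples)
    if df.index.duplicated().any():
        raise ParseError(f"{genes_path}: duplicate gene identifiers")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA",
              index_label=index_label)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"species", "organ"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: metadata missing columns {sorted(missing)}")
    if "relative_time" not in df.columns and "weight_mg" not in df.columns:
        raise ParseError(f"{path}: metadata needs 'relative_time' or 'weight_mg'")
    return df


def read_orthology(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: orthology table needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    return df


def pair_orthologues(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                     orthology: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align the two species' count tables on 1:1 orthologue pairs.

    Rows of the orthology table that are not one-to-one are rejected; genes
    absent from either table are dropped (with a logged count). Output rows
    are labelled 'gene_a|gene_b' and sorted, so the result is invariant to
    the row order of the inputs.
    """
    orth = orthology.copy()
    dup_a = orth["gene_a"].duplicated(keep=False)
    dup_b = orth["gene_b"].duplicated(keep=False)
    if (dup_a | dup_b).any():
        bad = orth.loc[dup_a | dup_b]
        raise ParseError(
            f"orthology table is not one-to-one: {len(bad)} rows involve a "
            f"repeated gene (e.g. {bad.iloc[0].tolist()})")
    present = orth["gene_a"].isin(counts_a.index) & orth["gene_b"].isin(counts_b.index)
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("pair_orthologues: dropped %d pairs absent from a count table", n_dropped)
    orth = orth.loc[present].sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    pair_ids = orth["gene_a"] + "|" + orth["gene_b"]
    a = counts_a.loc[orth["gene_a"]].set_axis(pair_ids, axis=0)
    b = counts_b.loc[orth["gene_b"]].set_axis(pair_ids, axis=0)
    return a, b


def read_staging_observations(path: str | Path, stage_labels: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "stage_label" not in df.columns:
        raise ParseError(f"{path}: staging table needs a 'stage_label' column")
    unknown = set(df["stage_label"]) - set(stage_labels)
    if unknown:
        raise ParseError(f"{path}: unknown stage labels {sorted(unknown)}")
    df["stage"] = [stage_labels.index(s) for s in df["stage_label"]]
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, *, seed: int, config: dict,
                   inputs: dict[str, str] | None = None) -> Path:
    """Versioned JSON manifest: seeds, software version, file checksums."""
    from . import __version__

    outdir = Path(outdir)
    outputs = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            outputs[str(p.relative_to(outdir))] = sha256_of(p)
    manifest = {
        "package": "devocoevol",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": inputs or {},
        "outputs": outputs,
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def verify_checksums(expected: dict[str, str]) -> None:
    """Abort (raise) when any input file does not match its declared hash."""
    for path, digest in expected.items():
        actual = sha256_of(path)
        if actual != digest:
            raise ParseError(f"checksum mismatch for {path}: "
                             f"expected {digest}, found {actual}")
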