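"""Readers, writers and cross-validation for the tabular inputs and outputs.

Input formats
-------------
* count table: TSV matrix (ASVs as rows, first column header ``asv_id``,
  one column per sample) or BIOM (JSON v1 and HDF5 v2.1 dialects);
* metadata / qPCR / taxonomy / titrations: TSV with fixed headers;
* all outputs: TSV with deterministic row and column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import StudyDesign, infer_design, validate_metadata
from .errors import (
    DuplicateIdError,
    ExistsError,
    MissingMetadataError,
    ParseError,
    SchemaError,
)

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class Dataset:
    """Validated bundle of all molecular inputs.

    Attributes
    ----------
    counts
        ASV x sample integer read matrix.
    meta
        Sample metadata (one row per sample).
    qpcr
        Total 16S rRNA gene copies (g dry soil)^-1 per sample.
    taxonomy
        Ranked lineages plus a resolved ``display_family`` per ASV, or None.
    design
        Sampling design inferred from the metadata.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    qpcr: pd.Series
    taxonomy: pd.DataFrame | None
    design: StudyDesign


# ---------------------------------------------------------------------------
# readers

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "asv_id":
        raise SchemaError(f"{path}: first column header must be 'asv_id', got {header[:1]}")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise DuplicateIdError(f"{path}: duplicate sample ids {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col="asv_id")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"{path}: duplicate ASV ids {dups}")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing values in count matrix")
    vals = df.to_numpy()
    if not np.allclose(vals, np.round(vals)) or (vals < 0).any():
        raise SchemaError(f"{path}: counts must be non-negative integers")
    return df.astype(np.int64)


def read_counts_biom(path: str | Path) -> pd.DataFrame:
    """Read a BIOM table (JSON v1 or HDF5 v2.1) into an ASV x sample frame."""
    path = Path(path)
    if h5py.is_hdf5(path):
        return _read_biom_hdf5(path)
    return _read_biom_json(path)


def _read_biom_hdf5(path: Path) -> pd.DataFrame:
    from scipy import sparse

    with h5py.File(path, "r") as f:
        try:
            obs_ids = [x.decode() if isinstance(x, bytes) else str(x)
                       for x in f["observation/ids"][:]]
            samp_ids = [x.decode() if isinstance(x, bytes) else str(x)
                        for x in f["sample/ids"][:]]
            grp = f["observation/matrix"]
            mat = sparse.csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
                shape=(len(obs_ids), len(samp_ids)),
            )
        except KeyError as exc:
            raise ParseError(f"{path}: not a BIOM 2.1 HDF5 file ({exc})") from exc
    df = pd.DataFrame(mat.toarray(), index=obs_ids, columns=samp_ids)
    df.index.name = "asv_id"
    return _check_biom_frame(df, path)


def _read_biom_json(path: Path) -> pd.DataFrame:
    try:
        with open(path) as fh:
            doc = json.load(fh)
        obs_ids = [r["id"] for r in doc["rows"]]
        samp_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        data = np.zeros(shape)
        if doc["matrix_type"] == "dense":
            data[:] = doc["data"]
        else:
            for i, j, v in doc["data"]:
                data[int(i), int(j)] = v
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: not a BIOM v1 JSON file ({exc})") from exc
    df = pd.DataFrame(data, index=obs_ids, columns=samp_ids)
    df.index.name = "asv_id"
    return _check_biom_frame(df, path)


def _check_biom_frame(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    if df.index.duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate observation ids")
    if pd.Index(df.columns).duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate sample ids")
    vals = df.to_numpy()
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        raise SchemaError(f"{path}: counts must be non-negative integers")
    return df.astype(np.int64)


def read_metadata(path: str | Path) -> pd.DataFrame:
    try:
        meta = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return validate_metadata(meta)


def read_qpcr(path: str | Path) -> pd.Series:
    """qPCR totals: TSV with columns ``sample_id`` and ``total_copies``."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("sample_id", "total_copies"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate sample ids")
    totals = df.set_index("sample_id")["total_copies"].astype(float)
    if (totals <= 0).any() or not np.isfinite(totals).all():
        raise SchemaError(f"{path}: qPCR totals must be strictly positive")
    return totals


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy: ``asv_id`` plus either one column per rank or a single
    semicolon-delimited ``lineage`` column. Adds ``display_family``."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "asv_id" not in df.columns:
        raise SchemaError(f"{path}: missing column 'asv_id'")
    if df["asv_id"].duplicated().any():
        raise DuplicateIdError(f"{path}: duplicate ASV ids in taxonomy")
    df = df.set_index("asv_id")
    if "lineage" in df.columns:
        parts = df["lineage"].str.split(";", expand=True).fillna("")
        parts = parts.apply(lambda c: c.str.strip())
        tax = pd.DataFrame("", index=df.index, columns=list(TAXONOMY_RANKS))
        for i, rank in enumerate(TAXONOMY_RANKS):
            if i < parts.shape[1]:
                tax[rank] = parts[i]
    else:
        missing = [r for r in TAXONOMY_RANKS if r not in df.columns]
        if missing:
            raise SchemaError(f"{path}: taxonomy missing ranks {missing}")
        tax = df[list(TAXONOMY_RANKS)].copy()
    tax["display_family"] = resolve_display_family(tax)
    return tax


def resolve_display_family(tax: pd.DataFrame) -> pd.Series:
    """Family name per ASV, falling back to the next named higher rank.

    ASVs without a family label are displayed under the nearest named higher
    rank (order, class, phylum, domain); fully unclassified ASVs become
    ``"Unclassified"``. The resulting label is never empty.
    """
    fallback_order = ("family", "order", "class", "phylum", "domain")
    out = pd.Series("Unclassified", index=tax.index, dtype=object)
    remaining = pd.Series(True, index=tax.index)
    for rank in fallback_order:
        vals = tax[rank].astype(str).str.strip()
        hit = remaining & (vals != "")
        if rank == "family":
            out[hit] = vals[hit]
        else:
            out[hit] = vals[hit] + f" ({rank})"
        remaining &= ~hit
    return out


def load_inputs(
    count_path: str | Path,
    meta_path: str | Path,
    qpcr_path: str | Path,
    taxonomy_path: str | Path | None = None,
    fmt: str = "tsv",
) -> Dataset:
    """Load and cross-validate all molecular inputs into a :class:`Dataset`."""
    if fmt == "tsv":
        counts = read_counts_tsv(count_path)
    elif fmt == "biom":
        counts = read_counts_biom(count_path)
    else:
        raise SchemaError(f"unknown count-table format {fmt!r}")
    meta = read_metadata(meta_path)
    qpcr = read_qpcr(qpcr_path)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None

    samples = list(counts.columns)
    no_meta = sorted(set(samples) - set(meta["sample_id"]))
    if no_meta:
        raise MissingMetadataError(f"samples in counts without metadata: {no_meta}")
    no_qpcr = sorted(set(samples) - set(qpcr.index))
    if no_qpcr:
        raise MissingMetadataError(f"samples in counts without qPCR totals: {no_qpcr}")
    meta = meta[meta["sample_id"].isin(samples)].reset_index(drop=True)
    qpcr = qpcr.loc[samples]
    if taxonomy is not None:
        no_tax = sorted(set(counts.index) - set(taxonomy.index))
        if no_tax:
            raise MissingMetadataError(f"ASVs in counts without taxonomy: {no_tax}")
        taxonomy = taxonomy.loc[counts.index]
    design = infer_design(meta)
    return Dataset(counts=counts, meta=meta, qpcr=qpcr, taxonomy=taxonomy, design=design)


# ---------------------------------------------------------------------------
# writers

def _sorted_frame(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.name is not None:
        return df.sort_index()
    return df


def write_results(
    results: dict[str, pd.DataFrame | pd.Series],
    out_dir: str | Path,
    overwrite: bool = False,
) -> list[Path]:
    """Write every result table as ``<name>.tsv`` under ``out_dir``.

    Rows are sorted by index (when the index is named), column order is
    preserved, and floats use a fixed repr so identical inputs yield
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(results):
        target = out_dir / f"{name}.tsv"
        if target.exists() and not overwrite:
            raise ExistsError(f"{target} exists and overwrite is False")
        obj = results[name]
        if isinstance(obj, pd.Series):
            obj = obj.to_frame()
        obj = _sorted_frame(obj)
        obj.to_csv(target, sep="\t", index=obj.index.name is not None,
                   lineterminator="\n", float_format="%.10g")
        paths.append(target)
    return paths
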