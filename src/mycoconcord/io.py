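"""Readers and writers for feature tables, taxonomy and metadata.

Feature tables are plain TSV with samples as rows (first column the sample
ID) and features as columns.  The reader also accepts the transposed
orientation and classic BIOM-style TSV exports (``#OTU ID`` header, features
as rows, optional trailing taxonomy column); orientation is auto-detected
against a set of known sample IDs when provided.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import FeatureTable


def _read_raw_tsv(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        # Classic BIOM TSV export: optional comment line then "#OTU ID" header.
        if first.startswith("# Constructed from biom"):
            first = fh.readline()
        if first.lstrip("#").strip().lower().startswith("otu id"):
            df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
            df.columns = [c.strip() for c in first.lstrip("#").strip().split("\t")[1:]]
            if df.columns[-1].lower() in {"taxonomy", "consensus lineage"}:
                df = df.drop(columns=df.columns[-1])
            return df.T.apply(pd.to_numeric)  # samples as rows
        header = [h.strip() for h in first.rstrip("\n").split("\t")[1:]]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"{path}: duplicated IDs in header: {dupes}")
    return pd.read_csv(path, sep="\t", index_col=0)


def read_feature_table(
    path: str | Path,
    units: str,
    sample_ids: list[str] | None = None,
) -> FeatureTable:
    """Read a TSV (or classic BIOM-style TSV) table as a FeatureTable.

    Parameters
    ----------
    path:
        Input file.
    units:
        Units tag to attach (``counts``, ``relative``, ...).
    sample_ids:
        Known sample IDs (typically from the metadata) used to auto-detect
        orientation; the table is transposed if its columns, not its rows,
        match them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_raw_tsv(path)
    if df.index.has_duplicates or df.columns.has_duplicates:
        dupes = list(df.index[df.index.duplicated()]) + list(
            df.columns[df.columns.duplicated()]
        )
        raise ValueError(f"{path}: duplicated IDs: {sorted(set(map(str, dupes)))}")
    if sample_ids is not None:
        row_hits = df.index.isin(sample_ids).sum()
        col_hits = df.columns.isin(sample_ids).sum()
        if col_hits > row_hits:
            df = df.T
        elif row_hits == 0:
            raise ValueError(f"{path}: no known sample IDs found on either axis")
    bad = df.map(lambda v: isinstance(v, str)).to_numpy()
    if bad.any():
        i, j = next(zip(*bad.nonzero()))
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns.name = None
    return FeatureTable(df.astype(float), units=units, provenance=(f"read:{path.name}",))


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.rename_axis("sample_id").to_csv(path, sep="\t")
    return path


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column (feature_id, lineage) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated feature IDs: {dupes}")
    return df.iloc[:, 0].to_dict()


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV indexed by its first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample IDs: {dupes}")
    return df


def read_blacklist(path: str | Path) -> set[str]:
    """Read one feature ID per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
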