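"""Reading and writing the tables the tool touches.

Expression matrices are delimited text (TSV/CSV) with one header row and a
gene-symbol key column; sample metadata is TSV with a required ``sample_id``
column. Gene symbols are canonicalized on load (uppercased, alias-mapped) so
panel matching survives case noise and known symbol typos.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "ResultBundle",
    "canonicalize_gene",
    "read_expression_matrix",
    "read_sample_table",
    "write_results",
    "read_results",
]

RESERVED_META_COLUMNS = (
    "sample_id",
    "patient_id",
    "tissue",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
)


def _load_alias_map() -> dict:
    with resources.files("ehbmt.data").joinpath("gene_aliases.json").open() as fh:
        return json.load(fh)


_ALIAS_MAP = _load_alias_map()


def canonicalize_gene(symbol: str) -> str:
    """Uppercase, strip, and alias-map a gene symbol.

    Idempotent: the alias map is keyed and valued in canonical (uppercase)
    form, and map values are never themselves alias keys.
    """
    s = str(symbol).strip().upper()
    return _ALIAS_MAP.get(s, s)


@dataclass
class ExpressionMatrix:
    """Numeric gene x sample table.

    ``values`` is a pandas DataFrame indexed by canonical gene symbols with
    sample ids as columns. ``normalized`` records the scale of the values:
    ``raw``, ``log`` or ``zscore``.
    """

    values: pd.DataFrame
    normalized: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after canonicalization: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("no data rows")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class SampleTable:
    """Per-sample metadata: identity, tissue status, survival, covariates.

    Unknown columns are retained as clinical covariates; blank covariate
    cells become the explicit category ``"Missing"``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValueError("metadata must contain a sample_id column")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id: {dups}")
        for col in ("os_event", "dfs_event"):
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if not vals.isin([0, 1]).all():
                    raise ValueError(f"{col} values must be 0 or 1")
        if "tissue" in self.data.columns:
            vals = self.data["tissue"].dropna()
            bad = set(vals.unique()) - {"normal", "tumor"}
            if bad:
                raise ValueError(f"tissue values must be 'normal' or 'tumor', got {sorted(bad)}")
        self.data = self.data.set_index("sample_id", drop=False)
        self.data.index.name = None  # keep "sample_id" unambiguous for merges

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    @property
    def covariates(self) -> list:
        return [c for c in self.data.columns if c not in RESERVED_META_COLUMNS]


@dataclass
class ResultBundle:
    """Everything one run produces: assignments, statistics, run metadata."""

    assignments: pd.DataFrame
    statistics: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path, orientation: str = "genes_in_rows", sep: Optional[str] = None
) -> ExpressionMatrix:
    """Load a delimited expression table.

    The first column holds the key (gene symbols for ``genes_in_rows``,
    sample ids for ``samples_in_rows``). No orientation auto-detection:
    silent transposition is a classic corruption source. Duplicate gene rows
    (after canonicalization) are collapsed by mean with a warning.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = sep or _sniff_sep(path)
    if orientation == "genes_in_rows":
        # pandas silently renames duplicate header fields; check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        keys = [h.strip() for h in header[1:]]
        dups = {k for k in keys if keys.count(k) > 1}
        if dups:
            raise ValueError(f"{path}: duplicate sample id {sorted(dups)[0]!r}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows")
    if orientation == "samples_in_rows":
        df = df.T
    # locate non-numeric cells before coercion so the error names them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    numeric.index = [canonicalize_gene(g) for g in numeric.index]
    numeric.columns = [str(c).strip() for c in numeric.columns]
    if pd.Index(numeric.columns).has_duplicates:
        dup = pd.Index(numeric.columns)
        raise ValueError(f"{path}: duplicate sample id {dup[dup.duplicated()][0]!r}")
    if numeric.index.has_duplicates:
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        warnings.warn(
            f"{path}: duplicate gene rows collapsed by mean: {sorted(set(dups))}",
            stacklevel=2,
        )
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(values=numeric, normalized="raw")


def read_sample_table(path, sep: str = "\t") -> SampleTable:
    """Load sample metadata. Blank covariate cells become 'Missing'."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "patient_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column sample_id")
    for col in ("os_event", "dfs_event"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            nonblank = df[col].notna()
            if (vals[nonblank].isna() | ~vals[nonblank].isin([0, 1])).any():
                raise ValueError(f"{path}: {col} values must be 0, 1 or blank")
            df[col] = vals
    for col in ("os_time", "dfs_time"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in df.columns:
        if col not in RESERVED_META_COLUMNS:
            df[col] = df[col].astype("object")
            df[col] = df[col].where(df[col].notna(), "Missing")
            df[col] = df[col].replace("", "Missing")
    return SampleTable(data=df)


def write_results(bundle: ResultBundle, directory) -> dict:
    """Write a ResultBundle to ``directory``; returns a manifest of files.

    Assignments and statistics go to TSV, run metadata to JSON. An empty
    statistics section writes no file and is noted in the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"directory": str(directory), "files": [], "omitted": []}

    apath = directory / "assignments.tsv"
    bundle.assignments.to_csv(apath, sep="\t", index=False)
    manifest["files"].append(apath.name)

    if bundle.statistics:
        for name, table in bundle.statistics.items():
            spath = directory / f"stats_{name}.tsv"
            pd.DataFrame(table).to_csv(spath, sep="\t")
            manifest["files"].append(spath.name)
    else:
        manifest["omitted"].append("statistics (empty)")

    mpath = directory / "run_metadata.json"
    with open(mpath, "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True, default=str)
    manifest["files"].append(mpath.name)

    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_results(directory) -> ResultBundle:
    """Read back a ResultBundle written by :func:`write_results`."""
    directory = Path(directory)
    assignments = pd.read_csv(directory / "assignments.tsv", sep="\t")
    statistics = {}
    for spath in sorted(directory.glob("stats_*.tsv")):
        name = spath.stem[len("stats_"):]
        statistics[name] = pd.read_csv(spath, sep="\t", index_col=0)
    with open(directory / "run_metadata.json") as fh:
        metadata = json.load(fh)
    return ResultBundle(assignments=assignments, statistics=statistics, metadata=metadata)
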