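"""Readers/writers for the tabular and gene-set formats used throughout.

Expression matrices are delimited text (TSV or CSV, autodetected from the
extension) with gene rows and sample columns by default.  Gene sets use the
standard GMT layout (name, description, member genes); because GMT has no
slot for a sign, the direction of a signature in the TMEscore sum is encoded
in the description field as ``+1`` / ``-1`` (anything else defaults to +1
with a warning).  Clinical tables are TSV/CSV with a ``sample_id`` column and
any of ``response`` (RECIST: CR/PR -> 1, SD/PD -> 0), ``time``/``event`` and
``subtype``.

Gene identifiers are opaque, case-sensitive strings: no symbol aliasing is
performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

Scale = Literal["linear_counts", "log2", "zscored"]
_SCALES = ("linear_counts", "log2", "zscored")

RESPONSE_CODES = {"CR": 1, "PR": 1, "SD": 0, "PD": 0, "1": 1, "0": 0}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with an explicit scale tag.

    ``scale`` records what the numbers are: non-negative ``linear_counts``
    (NanoString-style), ``log2`` normalized values, or ``zscored`` rows.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale = "log2"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 1:
            raise ValidationError("expression matrix needs at least 1 gene")
        if len(self.sample_ids) < 2:
            raise ValidationError("expression matrix needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.scale == "linear_counts" and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: Scale = "log2") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Submatrix restricted to ``genes`` (which must all be present)."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows], self.scale)


@dataclass
class GeneSignature:
    """A named gene set with a direction (+1 immune/'A-type', -1 stromal/'B-type')."""

    name: str
    genes: list[str]
    direction: int = +1

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")
        if self.direction not in (+1, -1):
            raise ValidationError(f"signature {self.name!r}: direction must be +1 or -1")
        _check_unique(self.genes, f"gene in signature {self.name!r}")


@dataclass
class SignatureCollection:
    signatures: list[GeneSignature] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.signatures], "signature")

    def __iter__(self):
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    def __getitem__(self, name: str) -> GeneSignature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations keyed by sample id.

    ``response``: 1 = responder (RECIST CR/PR), 0 = non-responder (SD/PD).
    ``time``/``event``: right-censored survival; both present or both absent.
    """

    data: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        has_time = "time" in df.columns
        has_event = "event" in df.columns
        if has_time != has_event:
            raise ValidationError("clinical table: time present iff event present")
        if has_time:
            t = pd.to_numeric(df["time"], errors="raise")
            if (t <= 0).any():
                bad = df.index[t <= 0][0]
                raise ValidationError(f"non-positive survival time for sample {bad!r}")
            ev = set(pd.unique(df["event"].dropna()))
            if not ev <= {0, 1, 0.0, 1.0}:
                raise ValidationError(f"event values must be 0/1, got {sorted(ev)}")
        if "response" in df.columns:
            rv = set(pd.unique(df["response"].dropna()))
            if not rv <= {0, 1, 0.0, 1.0}:
                raise ValidationError(f"response values must be 0/1, got {sorted(rv)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def response(self) -> pd.Series | None:
        return self.data["response"] if "response" in self.data.columns else None

    @property
    def time(self) -> pd.Series | None:
        return self.data["time"] if "time" in self.data.columns else None

    @property
    def event(self) -> pd.Series | None:
        return self.data["event"] if "event" in self.data.columns else None

    @property
    def subtype(self) -> pd.Series | None:
        return self.data["subtype"] if "subtype" in self.data.columns else None


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_table(
    path: str | Path,
    genes_in: Literal["rows", "columns"] = "rows",
    na_policy: Literal["error", "drop_gene"] = "error",
    scale: Scale = "log2",
) -> ExpressionMatrix:
    """Read a delimited genes x samples table into an :class:`ExpressionMatrix`.

    ``genes_in="columns"`` transposes after reading.  ``na_policy`` controls
    missing cells: ``error`` (default) aborts, ``drop_gene`` removes any gene
    row containing an NA before invariant checks.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    if genes_in == "columns":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id: {dup!r}")
    # locate non-numeric cells precisely rather than let the cast fail opaquely
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at gene {df.index[i]!r}, sample {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        if na_policy == "error":
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValidationError(
                f"missing value at gene {numeric.index[i]!r}, sample {numeric.columns[j]!r} "
                "(na_policy='error')"
            )
        dropped = numeric.index[numeric.isna().any(axis=1)]
        logger.warning("dropping %d gene(s) with missing values: %s",
                       len(dropped), list(dropped))
        numeric = numeric.dropna(axis=0)
    return ExpressionMatrix.from_frame(numeric, scale=scale)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV/CSV (by extension) with gene rows at full float precision."""
    matrix.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g",
                             index_label="gene_id")


def read_gmt(path: str | Path) -> SignatureCollection:
    """Parse a GMT file; the description field carries the direction (+1/-1)."""
    sigs: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected name, description "
                                  f"and at least one gene, got {len(fields)} field(s)")
            name, desc, *genes = fields
            desc = desc.strip()
            if desc in ("+1", "1"):
                direction = +1
            elif desc in ("-1", "−1"):
                direction = -1
            else:
                direction = +1
                warnings.warn(
                    f"{path}: line {lineno}: description {desc!r} is not +1/-1; "
                    f"defaulting signature {name!r} to direction +1"
                )
            uniq = list(dict.fromkeys(g for g in genes if g))
            if len(uniq) < len([g for g in genes if g]):
                warnings.warn(f"{path}: line {lineno}: duplicate genes in set "
                              f"{name!r} were de-duplicated")
            sigs.append(GeneSignature(name=name, genes=uniq, direction=direction))
    return SignatureCollection(sigs)


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, f"{s.direction:+d}", *s.genes]) + "\n")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV/CSV; maps RECIST codes CR/PR -> 1, SD/PD -> 0."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype={0: str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if "response" in df.columns:
        def _map(v):
            if pd.isna(v):
                return np.nan
            key = str(v).strip().upper()
            # accept "1.0"/"0.0" from numeric round-trips
            if key in ("1.0", "0.0"):
                key = key[0]
            if key not in RESPONSE_CODES:
                raise ValidationError(f"unknown response code {v!r} "
                                      "(expected CR/PR/SD/PD or 0/1)")
            return RESPONSE_CODES[key]
        df["response"] = df["response"].map(_map)
    if ("time" in df.columns) and ("event" not in df.columns):
        raise ValidationError("clinical table has 'time' but no 'event' column")
    if ("event" in df.columns) and ("time" not in df.columns):
        raise ValidationError("clinical table has 'event' but no 'time' column")
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep=_sep_for(path), index_label="sample_id")
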