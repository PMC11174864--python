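"""Readers and writers for every on-disk artifact of the pipeline.

All tabular artifacts are plain TSV/CSV; evaluation reports are JSON. Loading
is strict: duplicated identifiers, missing values, unknown split tags and
malformed interaction rows are hard errors rather than silent repairs, because
every downstream statistic (correlations, cosine similarities, graph spectra)
would quietly change under imputation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SPLITS = ("train", "validation", "test")

#: significant digits used by all float writers; round-trips double precision
FLOAT_FORMAT = "%.17g"


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Patients x genes expression levels.

    Rows are patients, columns genes; ``standardized`` records whether the
    values are raw expression levels or z-scores.
    """

    patient_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_p, n_g = self.values.shape
        if n_p != len(self.patient_ids) or n_g != len(self.gene_ids):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.gene_ids)} genes"
            )
        if n_p == 0 or n_g == 0:
            raise FormatError("expression matrix is empty")
        _check_unique(self.patient_ids, "patient")
        _check_unique(self.gene_ids, "gene")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at patient "
                f"{self.patient_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Column-subset preserving the requested gene order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        cols = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            patient_ids=list(self.patient_ids),
            gene_ids=list(gene_ids),
            values=self.values[:, cols].copy(),
            standardized=self.standardized,
        )


@dataclass
class SurvivalTable:
    """Per-patient survival time in months plus train/validation/test tag."""

    patient_ids: list[str]
    survival_time: np.ndarray
    split: list[str]

    def __post_init__(self) -> None:
        self.survival_time = np.asarray(self.survival_time, dtype=float)
        n = len(self.patient_ids)
        if self.survival_time.shape != (n,) or len(self.split) != n:
            raise FormatError("survival table fields have inconsistent lengths")
        _check_unique(self.patient_ids, "patient")
        if not np.isfinite(self.survival_time).all() or (self.survival_time < 0).any():
            raise FormatError("survival times must be finite and non-negative")
        bad = sorted(set(self.split) - set(VALID_SPLITS))
        if bad:
            raise FormatError(f"unknown split tag(s) {bad}; expected {VALID_SPLITS}")

    def mask(self, split: str) -> np.ndarray:
        if split not in VALID_SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return np.array([s == split for s in self.split])

    def reindex(self, patient_ids: list[str]) -> "SurvivalTable":
        """Reorder to match an expression matrix's patient order."""
        index = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in patient_ids if p not in index]
        if missing:
            raise FormatError(f"patients missing from survival table: {missing}")
        rows = [index[p] for p in patient_ids]
        return SurvivalTable(
            patient_ids=list(patient_ids),
            survival_time=self.survival_time[rows],
            split=[self.split[i] for i in rows],
        )


@dataclass
class InteractionEdgeList:
    """Gene-gene interactions: (source, type, target) rows.

    The interaction type is provenance metadata only; no model operation
    consumes it. ``n_duplicates_dropped`` and ``n_out_of_universe_dropped``
    record what loading discarded.
    """

    edges: list[tuple[str, str, str]] = field(default_factory=list)
    n_duplicates_dropped: int = 0
    n_out_of_universe_dropped: int = 0

    def __post_init__(self) -> None:
        for s, _t, d in self.edges:
            if s == d:
                raise FormatError(f"self-interaction on gene {s!r}")

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for s, _t, d in self.edges:
            out.add(s)
            out.add(d)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} identifier {x!r}")
        seen.add(x)


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "csv"):
        return "\t" if dialect == "tsv" else ","
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def load_expression(
    path: str | Path,
    dialect: str | None = None,
    transposed: bool = False,
    standardized: bool = False,
) -> ExpressionMatrix:
    """Load an expression matrix (first row gene ids, first column patient ids).

    ``transposed=True`` reads a genes-as-rows file; the in-memory orientation
    is always patients-as-rows. Duplicated identifiers, empty matrices and
    non-numeric cells are hard errors.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    col_ids = [c for c in header.split(sep)[1:]]
    # header parsed by hand: pandas would silently mangle duplicated ids
    _check_unique(col_ids, "patient" if transposed else "gene")
    df = pd.read_csv(path, sep=sep, index_col=0, header=0,
                     float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    row_ids = [str(i) for i in df.index]
    for j, dtype in enumerate(df.dtypes):
        if not np.issubdtype(dtype, np.number):
            col = df.iloc[:, j]
            for i, cell in enumerate(col):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    p, g = (col_ids[j], row_ids[i]) if transposed else (row_ids[i], col_ids[j])
                    raise FormatError(
                        f"{path}: non-numeric or missing value at patient {p!r}, gene {g!r}"
                    ) from None
    values = df.to_numpy(dtype=float)
    if transposed:
        row_ids, col_ids = col_ids, row_ids
        values = values.T
    mat = ExpressionMatrix(
        patient_ids=row_ids,
        gene_ids=col_ids,
        values=values,
        standardized=standardized,
    )
    logger.info(
        "loaded expression matrix %s: %d patients, %d genes",
        path, mat.n_patients, mat.n_genes,
    )
    return mat


def write_expression(matrix: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.patient_ids, columns=matrix.gene_ids)
    df.to_csv(path, sep=_sep_for(path, dialect), float_format=FLOAT_FORMAT)


def load_interactions(path: str | Path, gene_universe: set[str] | None = None) -> InteractionEdgeList:
    """Load a 3-column (source, interaction type, target) edge list.

    Restricts edges to pairs with both endpoints in ``gene_universe`` (the
    merge with the expression gene set), collapses duplicates and drops
    self-interactions, logging the counts.
    """
    path = Path(path)
    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    n_dup = n_out = n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            if lineno == 1 and fields[0].upper() in ("PARTICIPANT_A", "SOURCE", "SOURCE_GENE"):
                continue  # optional extended-SIF header row
            src, typ, dst = (f.strip() for f in fields)
            if src == dst:
                n_self += 1
                continue
            if gene_universe is not None and (src not in gene_universe or dst not in gene_universe):
                n_out += 1
                continue
            key = (src, typ, dst)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append(key)
    if gene_universe is not None and not edges:
        logger.warning("%s: no interactions left after restricting to the gene universe", path)
    logger.info(
        "loaded %d interactions from %s (%d duplicates, %d outside universe, %d self-loops dropped)",
        len(edges), path, n_dup, n_out, n_self,
    )
    return InteractionEdgeList(
        edges=edges, n_duplicates_dropped=n_dup, n_out_of_universe_dropped=n_out
    )


def write_interactions(edge_list: InteractionEdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, typ, dst in edge_list.edges:
            fh.write(f"{src}\t{typ}\t{dst}\n")


def load_survival(path: str | Path, expression: ExpressionMatrix | None = None) -> SurvivalTable:
    """Load a survival table (columns patient_id, survival_months, split).

    If ``expression`` is given, every expression patient must be present and
    the returned table is reordered to the expression patient order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "split": str},
                     float_precision="round_trip")
    required = {"patient_id", "survival_months", "split"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    table = SurvivalTable(
        patient_ids=[str(p) for p in df["patient_id"]],
        survival_time=df["survival_months"].to_numpy(dtype=float),
        split=[str(s) for s in df["split"]],
    )
    if expression is not None:
        missing = [p for p in expression.patient_ids if p not in set(table.patient_ids)]
        if missing:
            raise FormatError(f"{path}: patients missing from survival table: {missing}")
        table = table.reindex(expression.patient_ids)
    return table


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": table.patient_ids,
            "survival_months": table.survival_time,
            "split": table.split,
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def load_pseudo_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if not {"patient_id", "pseudo_label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns patient_id, pseudo_label")
    return [str(p) for p in df["patient_id"]], df["pseudo_label"].to_numpy(dtype=int)


def write_pseudo_labels(patient_ids: list[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"patient_id": patient_ids, "pseudo_label": np.asarray(labels, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def load_representations(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Load a patient-indexed representation matrix (patients x dims)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return [str(p) for p in df.index], df.to_numpy(dtype=float)


def write_representations(patient_ids: list[str], H: np.ndarray, path: str | Path) -> None:
    H = np.asarray(H, dtype=float)
    pd.DataFrame(H, index=patient_ids, columns=[f"dim{j}" for j in range(H.shape[1])]).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT
    )


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
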