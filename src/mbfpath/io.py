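"""Reading and writing the package's plain-text formats.

* dense mutation matrix — TSV, header row of gene labels (first cell is a
  corner label), one row per patient, entries 0/1; comment lines start
  with ``#`` and the writer emits ``#orientation=patients_x_genes``;
* sparse mutation matrix — two-column TSV of (patient_label, gene_label)
  pairs; duplicates collapse to a single 1;
* covariate table — TSV with columns gene, expression, replication_time,
  chromosome_status;
* reference driver list — one gene symbol per line;
* results — TSV or JSON records of identified pathways (JSON round-trips
  losslessly).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import GeneSet, InputError, MutationMatrix, PathwayResult
from .fusion import CovariateTable

__all__ = [
    "ParseError",
    "read_mutation_matrix",
    "write_mutation_matrix",
    "read_covariates",
    "write_covariates",
    "read_reference",
    "write_results",
    "read_results",
]

COVARIATE_COLUMNS = ("gene", "expression", "replication_time", "chromosome_status")


class ParseError(InputError):
    """Malformed input file; the message carries the offending line number."""


def _data_lines(path: Path):
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _read_dense(path: Path) -> MutationMatrix:
    rows = []
    patient_ids = []
    gene_ids: Optional[list[str]] = None
    header_width = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if gene_ids is None:
            gene_ids = fields[1:]
            header_width = len(fields)
            if not gene_ids:
                raise ParseError(f"{path}:{lineno}: header row has no gene labels")
            continue
        if len(fields) != header_width:
            raise ParseError(
                f"{path}:{lineno}: ragged row — {len(fields)} fields, expected {header_width}"
            )
        patient_ids.append(fields[0])
        row = []
        for j, cell in enumerate(fields[1:]):
            if cell not in ("0", "1"):
                raise ParseError(
                    f"{path}:{lineno}: non-binary entry {cell!r} for patient "
                    f"{fields[0]!r}, gene {gene_ids[j]!r}"
                )
            row.append(int(cell))
        rows.append(row)
    if gene_ids is None:
        raise ParseError(f"{path}: file contains no data")
    if not rows:
        raise ParseError(f"{path}: no patient rows after the header")
    try:
        return MutationMatrix(np.array(rows, dtype=np.uint8), patient_ids, gene_ids)
    except InputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_sparse(path: Path) -> MutationMatrix:
    patients: dict[str, int] = {}
    genes: dict[str, int] = {}
    pairs = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        p, g = fields
        patients.setdefault(p, len(patients))
        genes.setdefault(g, len(genes))
        pairs.add((patients[p], genes[g]))
    if not pairs:
        raise ParseError(f"{path}: file contains no (patient, gene) pairs")
    entries = np.zeros((len(patients), len(genes)), dtype=np.uint8)
    for i, j in pairs:
        entries[i, j] = 1
    return MutationMatrix(entries, list(patients), list(genes))


def read_mutation_matrix(path: Union[str, Path], format: str = "dense") -> MutationMatrix:
    """Read a binary mutation matrix from a dense or sparse TSV file."""
    path = Path(path)
    if format == "dense":
        return _read_dense(path)
    if format == "sparse":
        return _read_sparse(path)
    raise InputError(f"unknown matrix format {format!r}; use 'dense' or 'sparse'")


def write_mutation_matrix(matrix: MutationMatrix, path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("#orientation=patients_x_genes\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient", *matrix.gene_ids])
        for i, pid in enumerate(matrix.patient_ids):
            writer.writerow([pid, *matrix.entries[i].tolist()])


def read_covariates(path: Union[str, Path]) -> CovariateTable:
    """Read the per-gene covariate TSV (gene, expression, replication_time, chromosome_status)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in COVARIATE_COLUMNS[1:]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {df[col][row]!r} in column {col!r} "
                f"(data row {row + 1})"
            )
        if values.isna().any():
            row = int(values.isna().idxmax())
            raise ParseError(f"{path}: missing value in column {col!r} (data row {row + 1})")
        df[col] = values
    try:
        return CovariateTable(
            tuple(df["gene"].astype(str)),
            df["expression"].to_numpy(),
            df["replication_time"].to_numpy(),
            df["chromosome_status"].to_numpy(),
        )
    except InputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_covariates(table: CovariateTable, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "gene": table.gene_ids,
            "expression": table.expression,
            "replication_time": table.replication_time,
            "chromosome_status": table.chromosome_status,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_reference(path: Union[str, Path]) -> set[str]:
    """Read a reference driver-gene list, one symbol per line."""
    symbols = {line.strip() for _, line in _data_lines(Path(path))}
    if not symbols:
        raise ParseError(f"{path}: reference gene list is empty")
    return symbols


def _result_record(res: PathwayResult, gene_ids: Sequence[str]) -> dict:
    return {
        "k": res.k,
        "genes": list(res.gene_set.labels(gene_ids)),
        "weight": res.weight,
        "coverage": res.coverage,
        "mutex_degree": res.mutex_degree,
        "p_value": res.p_value,
        "seed": res.seed,
    }


def write_results(
    results: Sequence[PathwayResult],
    path: Union[str, Path],
    gene_ids: Sequence[str],
    format: str = "tsv",
    parameters: Optional[dict] = None,
) -> None:
    """Serialize pathway results as TSV rows or a lossless JSON document."""
    if not results:
        raise InputError("no results to write")
    path = Path(path)
    records = [_result_record(r, gene_ids) for r in results]
    if format == "json":
        doc = {
            "parameters": parameters or {},
            "gene_ids": list(gene_ids),
            "results": [
                {**rec, "gene_indices": list(res.gene_set.indices)}
                for rec, res in zip(records, results)
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            if parameters:
                fh.write("#" + json.dumps(parameters, sort_keys=True) + "\n")
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["k", "genes", "weight", "coverage", "mutex_degree", "p_value", "seed"]
            )
            for rec in records:
                writer.writerow(
                    [
                        rec["k"],
                        ",".join(rec["genes"]),
                        f"{rec['weight']:.6g}",
                        f"{rec['coverage']:.6g}",
                        f"{rec['mutex_degree']:.6g}",
                        "" if rec["p_value"] is None else f"{rec['p_value']:.6g}",
                        rec["seed"],
                    ]
                )
    else:
        raise InputError(f"unknown results format {format!r}; use 'tsv' or 'json'")


def read_results(path: Union[str, Path]) -> list[PathwayResult]:
    """Read back pathway results written as JSON."""
    doc = json.loads(Path(path).read_text())
    out = []
    for rec in doc["results"]:
        out.append(
            PathwayResult(
                gene_set=GeneSet(tuple(rec["gene_indices"])),
                weight=rec["weight"],
                coverage=rec["coverage"],
                mutex_degree=rec["mutex_degree"],
                k=rec["k"],
                seed=rec["seed"],
                p_value=rec["p_value"],
            )
        )
    return out
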