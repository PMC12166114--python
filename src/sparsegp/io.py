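"""File formats: labelled CSV matrices, long phenotype tables, sparse
triplet weight exports, partition and metadata JSON.

Conventions: matrices travel as dense CSV with a header row and an index
column; phenotypes as long-format CSV ``genotype_id,trait_id,value``
(records keep file order); sparse weights and coefficient paths as triplet
TSV with **1-based** indices, matching the convention of the scripted
workflows this package mirrors.  Internal indices are always 0-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grm import MarkerMatrix, RelationshipMatrix
from .sgp import SGPResult, StackedPhenotypeIndex
from .solvers import CoefficientPath

__all__ = [
    "read_square_csv", "write_square_csv",
    "read_matrix_csv", "write_matrix_csv",
    "read_marker_csv", "write_marker_csv",
    "read_phenotypes_csv", "write_phenotypes_csv",
    "read_partition_json", "write_partition_json",
    "write_coefficient_path", "write_weights_tsv",
    "write_predictions_tsv", "write_metadata",
]


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".txt"} else ","


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def read_square_csv(path: str | Path) -> RelationshipMatrix:
    """Read a labelled square matrix (K, Omega, R) from CSV/TSV."""
    df = pd.read_csv(path, sep=_sep(Path(path)), index_col=0)
    values = df.to_numpy(dtype=np.float64)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: matrix is {values.shape[0]}x{values.shape[1]}, not square"
        )
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column labels disagree")
    return RelationshipMatrix(values=values,
                              genotype_ids=list(df.index.astype(str)))


def write_square_csv(path: str | Path, values: np.ndarray,
                     labels: Sequence[str]) -> None:
    labels = [str(x) for x in labels]
    pd.DataFrame(np.asarray(values), index=labels, columns=labels).to_csv(
        path, sep=_sep(Path(path)))


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled rectangular matrix (e.g. Gamma); returns
    (values, row_labels, col_labels)."""
    df = pd.read_csv(path, sep=_sep(Path(path)), index_col=0)
    return (df.to_numpy(dtype=np.float64),
            list(df.index.astype(str)), list(df.columns.astype(str)))


def write_matrix_csv(path: str | Path, values: np.ndarray,
                     row_labels: Sequence[str],
                     col_labels: Sequence[str]) -> None:
    pd.DataFrame(np.asarray(values), index=[str(x) for x in row_labels],
                 columns=[str(x) for x in col_labels]).to_csv(
        path, sep=_sep(Path(path)))


# ---------------------------------------------------------------------------
# markers and phenotypes
# ---------------------------------------------------------------------------


def read_marker_csv(path: str | Path) -> MarkerMatrix:
    """Marker CSV: genotypes in rows, marker-ID header, genotype-ID first
    column."""
    df = pd.read_csv(path, sep=_sep(Path(path)), index_col=0)
    return MarkerMatrix(values=df.to_numpy(dtype=np.float64),
                        genotype_ids=list(df.index.astype(str)),
                        marker_ids=list(df.columns.astype(str)))


def write_marker_csv(path: str | Path, markers: MarkerMatrix) -> None:
    pd.DataFrame(markers.values, index=markers.genotype_ids,
                 columns=markers.marker_ids).to_csv(path, sep=_sep(Path(path)))


def read_phenotypes_csv(
    path: str | Path,
    genotype_ids: Sequence[str],
) -> tuple[np.ndarray, StackedPhenotypeIndex, list[str]]:
    """Read a long phenotype table against a known genotype label set.

    Rows become records in file order.  Returns (y, index, trait_labels);
    the index has all records as training and an empty testing set —
    callers install a partition afterwards.  Unknown genotype IDs are an
    error reported with the offending labels.
    """
    df = pd.read_csv(path, sep=_sep(Path(path)))
    required = {"genotype_id", "trait_id", "value"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    lookup = {str(g): i for i, g in enumerate(genotype_ids)}
    gids = df["genotype_id"].astype(str)
    unknown = sorted(set(gids) - set(lookup))
    if unknown:
        raise ValueError(
            f"{path}: genotype ids absent from K: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    trait_labels = list(dict.fromkeys(df["trait_id"].astype(str)))
    t_lookup = {t: i for i, t in enumerate(trait_labels)}
    ID_geno = np.array([lookup[g] for g in gids], dtype=np.intp)
    ID_trait = np.array([t_lookup[t] for t in df["trait_id"].astype(str)],
                        dtype=np.intp)
    y = df["value"].to_numpy(dtype=np.float64)
    index = StackedPhenotypeIndex(ID_geno, ID_trait,
                                  trn=np.arange(len(df)), tst=[])
    return y, index, trait_labels


def write_phenotypes_csv(
    path: str | Path,
    y: np.ndarray,
    index: StackedPhenotypeIndex,
    genotype_ids: Sequence[str],
    trait_labels: Sequence[str] | None = None,
    records: np.ndarray | None = None,
) -> None:
    records = (np.arange(index.n_records) if records is None
               else np.asarray(records, dtype=np.intp))
    traits = ([str(t) for t in trait_labels] if trait_labels is not None
              else [f"T{t + 1}" for t in range(index.n_traits)])
    pd.DataFrame({
        "genotype_id": [genotype_ids[g] for g in index.ID_geno[records]],
        "trait_id": [traits[t] for t in index.ID_trait[records]],
        "value": np.asarray(y, dtype=np.float64)[records],
    }).to_csv(path, index=False, sep=_sep(Path(path)))


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------


def read_partition_json(path: str | Path, n_records: int
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Partition JSON with 1-based record indices; returns 0-based
    (trn, tst, meta)."""
    data = json.loads(Path(path).read_text())
    trn = np.asarray(data["trn"], dtype=np.intp) - 1
    tst = np.asarray(data["tst"], dtype=np.intp) - 1
    for name, idx in (("trn", trn), ("tst", tst)):
        if idx.size and (idx.min() < 0 or idx.max() >= n_records):
            raise ValueError(f"{path}: {name} indices out of range (1-based)")
    meta = {k: v for k, v in data.items() if k not in ("trn", "tst")}
    return trn, tst, meta


def write_partition_json(path: str | Path, index: StackedPhenotypeIndex,
                         seed: int | None = None) -> None:
    data = {
        "trn": (index.trn + 1).tolist(),
        "tst": (index.tst + 1).tolist(),
    }
    if seed is not None:
        data["seed"] = seed
    Path(path).write_text(json.dumps(data))


# ---------------------------------------------------------------------------
# sparse exports
# ---------------------------------------------------------------------------


def write_coefficient_path(path_prefix: str | Path,
                           path_obj: CoefficientPath) -> tuple[Path, Path]:
    """Coefficient path as triplet TSV plus a lambda-grid sidecar.

    Triplets (1-based): lambda_index, response_index, predictor_index,
    value.  The sidecar ``<prefix>.lambda.tsv`` lists lambda_index, lambda.
    """
    prefix = Path(path_prefix)
    rows = []
    for k, C in enumerate(path_obj.coefficients):
        coo = C.tocoo()
        for r, c, v in zip(coo.row, coo.col, coo.data):
            if v != 0:
                rows.append((k + 1, c + 1, r + 1, v))
    trip = pd.DataFrame(rows, columns=["lambda_index", "response_index",
                                       "predictor_index", "value"])
    trip_path = prefix.with_suffix(".path.tsv")
    trip.to_csv(trip_path, sep="\t", index=False)
    lam_path = prefix.with_suffix(".lambda.tsv")
    pd.DataFrame({"lambda_index": np.arange(1, path_obj.n_lambda + 1),
                  "lambda": path_obj.lambdas}).to_csv(
        lam_path, sep="\t", index=False)
    return trip_path, lam_path


def write_weights_tsv(path: str | Path, result: SGPResult,
                      lambda_indices: Sequence[int] | None = None) -> None:
    """SGP weights as triplet TSV: lambda_index, tst_record, trn_record,
    value (1-based; record numbers refer to the phenotype-table order)."""
    lam_idx = (range(result.n_lambda) if lambda_indices is None
               else lambda_indices)
    rows = []
    for k in lam_idx:
        coo = result.weights[k].tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if v != 0:
                rows.append((k + 1, int(result.index.tst[i]) + 1,
                             int(result.index.trn[j]) + 1, v))
    pd.DataFrame(rows, columns=["lambda_index", "tst_record", "trn_record",
                                "value"]).to_csv(path, sep="\t", index=False)


def write_predictions_tsv(path: str | Path, result: SGPResult) -> None:
    """Predictions as long TSV: record (1-based), lambda, value."""
    if result.predictions is None:
        raise ValueError("result holds no predictions (no y was supplied)")
    rows = []
    for k in range(result.n_lambda):
        for i, rec in enumerate(result.index.tst):
            rows.append((int(rec) + 1, result.lambdas[k],
                         result.predictions[k, i]))
    pd.DataFrame(rows, columns=["record", "lambda", "value"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run metadata
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_metadata(path: str | Path, inputs: dict[str, str | Path],
                   **params) -> None:
    """Reproducibility record: package version, input hashes, parameters."""
    meta = {
        "version": __version__,
        "inputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                   for name, p in inputs.items() if p is not None},
        "parameters": params,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
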