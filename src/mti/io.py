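"""Readers and writers for the three input tables and the result files.

All tables are UTF-8 CSV with a header row.  The compatibility matrix is
accepted in two dialects: the canonical long format
(``strain_a,strain_b,result``) and a wide square-matrix format (header row
and column of strain ids, cells ``1``/``0``/``NA``, diagonal ``-``),
auto-detected from the header shape.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    Compatibility,
    CompatibilityMatrix,
    Dataset,
    LociConsistencyTable,
    LociRelation,
    MTIError,
    OWE_SOJ_TOKENS,
    PairKey,
    ParentTable,
    ParseError,
    pair_key,
    relations_to_token,
)

__all__ = [
    "read_parent_table",
    "read_compatibility",
    "read_loci_table",
    "write_parent_table",
    "write_compatibility",
    "write_loci_table",
    "build_dataset",
    "load_dataset",
    "write_result",
]

PathLike = Union[str, Path]

_LONG_HEADER = ["strain_a", "strain_b", "result"]


def _read_csv(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, na_filter=False, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read CSV {path}: {exc}") from exc


def read_parent_table(path: PathLike) -> ParentTable:
    """Parse the monokaryon parent table (``strain_id,dikaryon_id``)."""
    df = _read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["strain_id", "dikaryon_id"]:
        raise ParseError(f"parent table header must be strain_id,dikaryon_id; got {list(df.columns)}")
    entries = []
    for _, row in df.iterrows():
        strain = str(row.iloc[0]).strip()
        dik = str(row.iloc[1]).strip()
        if not strain or not dik:
            raise ParseError("parent table: empty field")
        entries.append((strain, dik))
    try:
        return ParentTable(tuple(entries))
    except MTIError as exc:
        raise ParseError(f"parent table: {exc}") from exc


def _is_long_matrix(path: PathLike) -> bool:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    cells = [c.strip().lower() for c in header.rstrip("\n").split(",")]
    return cells[:3] == _LONG_HEADER


_RESULT_TOKENS = {
    "compatible": Compatibility.COMPATIBLE,
    "incompatible": Compatibility.INCOMPATIBLE,
}

_WIDE_CELLS = {
    "1": Compatibility.COMPATIBLE,
    "0": Compatibility.INCOMPATIBLE,
}


def read_compatibility(path: PathLike, parents: ParentTable) -> CompatibilityMatrix:
    """Parse the compatibility matrix (long format, or wide auto-detected).

    Duplicate rows with consistent results collapse; conflicting duplicates
    (including symmetric ``(a,b)`` vs ``(b,a)`` conflicts) are parse errors.
    """
    if _is_long_matrix(path):
        return _read_compat_long(path, parents)
    return _read_compat_wide(path, parents)


def _read_compat_long(path: PathLike, parents: ParentTable) -> CompatibilityMatrix:
    df = _read_csv(path)
    known = set(parents.strains)
    obs: dict[PairKey, Compatibility] = {}
    for _, row in df.iterrows():
        a, b = str(row.iloc[0]).strip(), str(row.iloc[1]).strip()
        token = str(row.iloc[2]).strip().lower()
        if a == b:
            raise ParseError(f"compatibility matrix: self pair {a!r}")
        for s in (a, b):
            if s not in known:
                raise ParseError(f"compatibility matrix: unknown strain {s!r}")
        if token not in _RESULT_TOKENS:
            raise ParseError(f"compatibility matrix: invalid result token {token!r}")
        pk = pair_key(a, b)
        val = _RESULT_TOKENS[token]
        if pk in obs and obs[pk] is not val:
            raise ParseError(f"compatibility matrix: conflicting duplicate for pair {pk}")
        obs[pk] = val
    return CompatibilityMatrix(strains=parents.strains, observations=obs)


def _read_compat_wide(path: PathLike, parents: ParentTable) -> CompatibilityMatrix:
    df = pd.read_csv(path, dtype=str, na_filter=False, index_col=0, skipinitialspace=True)
    known = set(parents.strains)
    col_strains = [str(c).strip() for c in df.columns]
    row_strains = [str(r).strip() for r in df.index]
    for s in col_strains + row_strains:
        if s not in known:
            raise ParseError(f"compatibility matrix: unknown strain {s!r}")
    obs: dict[PairKey, Compatibility] = {}
    for r in row_strains:
        for c in col_strains:
            cell = str(df.at[r, c]).strip()
            if r == c:
                if cell not in {"-", ""}:
                    raise ParseError(f"compatibility matrix: diagonal cell for {r!r} must be '-'")
                continue
            if cell in {"", "NA", "na", "-"}:
                continue
            if cell not in _WIDE_CELLS:
                raise ParseError(f"compatibility matrix: invalid cell {cell!r} at ({r},{c})")
            pk = pair_key(r, c)
            val = _WIDE_CELLS[cell]
            if pk in obs and obs[pk] is not val:
                raise ParseError(f"compatibility matrix: conflicting duplicate for pair {pk}")
            obs[pk] = val
    # keep the header's strain universe so partial matrices stay partial
    strains = tuple(dict.fromkeys(col_strains + [r for r in row_strains if r not in col_strains]))
    return CompatibilityMatrix(strains=strains, observations=obs)


def read_loci_table(path: PathLike, matrix: CompatibilityMatrix) -> LociConsistencyTable:
    """Parse the A/B loci consistency table (``strain_a,strain_b,owe_soj``)."""
    df = _read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["strain_a", "strain_b", "owe_soj"]:
        raise ParseError(f"loci table header must be strain_a,strain_b,owe_soj; got {list(df.columns)}")
    records: dict[PairKey, tuple[LociRelation, LociRelation]] = {}
    for _, row in df.iterrows():
        a, b = str(row.iloc[0]).strip(), str(row.iloc[1]).strip()
        token = str(row.iloc[2]).strip()
        if token not in OWE_SOJ_TOKENS:
            raise ParseError(f"loci table: unknown OWE-SOJ token {token!r}")
        pk = pair_key(a, b)
        if matrix.lookup(a, b) is not Compatibility.INCOMPATIBLE:
            raise ParseError(f"loci table: record for pair {pk} that is not observed incompatible")
        rels = OWE_SOJ_TOKENS[token]
        if pk in records and records[pk] != rels:
            raise ParseError(f"loci table: conflicting duplicate record for pair {pk}")
        records[pk] = rels
    return LociConsistencyTable(records)


def write_parent_table(parents: ParentTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["strain_id", "dikaryon_id"])
        for strain, dik in parents.entries:
            w.writerow([strain, dik])


def write_compatibility(matrix: CompatibilityMatrix, path: PathLike) -> None:
    """Write the matrix in the canonical long format, pairs sorted."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LONG_HEADER)
        for pk in sorted(matrix.observations):
            w.writerow([pk[0], pk[1], matrix.observations[pk].value])


def write_loci_table(loci: LociConsistencyTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["strain_a", "strain_b", "owe_soj"])
        for pk in sorted(loci.records):
            a_rel, b_rel = loci.records[pk]
            w.writerow([pk[0], pk[1], relations_to_token(a_rel, b_rel)])


def build_dataset(
    parents: ParentTable,
    matrix: CompatibilityMatrix,
    loci: Optional[LociConsistencyTable] = None,
    autofill_siblings: bool = True,
) -> Dataset:
    """Assemble a dataset; sibling pairs absent from the matrix are filled
    in as compatible (same-dikaryon pairs are inherently compatible and are
    usually recorded without experimental testing)."""
    if autofill_siblings:
        present = set(matrix.strains)
        obs = dict(matrix.observations)
        for pk in sorted(parents.sibling_pairs):
            if pk[0] in present and pk[1] in present and pk not in obs:
                obs[pk] = Compatibility.COMPATIBLE
        matrix = CompatibilityMatrix(strains=matrix.strains, observations=obs)
    return Dataset(parents=parents, matrix=matrix, loci=loci or LociConsistencyTable({}))


def load_dataset(
    parents_path: PathLike,
    matrix_path: PathLike,
    loci_path: Optional[PathLike] = None,
    autofill_siblings: bool = True,
) -> Dataset:
    """Read all three tables and assemble a dataset."""
    parents = read_parent_table(parents_path)
    matrix = read_compatibility(matrix_path, parents)
    loci = read_loci_table(loci_path, matrix) if loci_path else None
    return build_dataset(parents, matrix, loci, autofill_siblings=autofill_siblings)


def write_result(result, out_prefix: PathLike) -> tuple[Path, Path]:
    """Write the per-strain assignment CSV and the structured JSON document.

    Returns the paths ``(<prefix>_assignments.csv, <prefix>_result.json)``.
    """
    if not result.assignments:
        raise MTIError("no assignments to write")
    prefix = Path(out_prefix)
    if prefix.parent != Path(""):
        prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = Path(f"{prefix}_assignments.csv")
    json_path = Path(f"{prefix}_result.json")

    with open(csv_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["strain_id", "combination_index", "a_allele", "b_allele", "mating_type"])
        for idx, asg in enumerate(result.assignments, start=1):
            for strain in sorted(asg.alleles):
                a, b = asg.alleles[strain]
                w.writerow([strain, idx, a, b, f"A{a}B{b}"])

    doc = {
        "best_score": result.best_score,
        "max_score": result.max_score,
        "n_optimal": result.n_optima,
        "truncated": result.truncated,
        "n_enumerated": result.n_enumerated,
        "assignments": [
            {
                "combination_index": idx,
                "allele_counts": {"a": ac[0], "b": ac[1]},
                "strains": {
                    s: {"a_allele": asg.alleles[s][0], "b_allele": asg.alleles[s][1],
                        "mating_type": asg.mating_type(s)}
                    for s in sorted(asg.alleles)
                },
            }
            for idx, (asg, ac) in enumerate(zip(result.assignments, result.allele_counts), start=1)
        ],
        "flagged_pairs": [
            {"strain_a": pk[0], "strain_b": pk[1], "reason": reason}
            for pk, reason in result.flagged_pairs
        ],
        "statistics": result.statistics.as_dict() if result.statistics is not None else None,
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, json_path
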