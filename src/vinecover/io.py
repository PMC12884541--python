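"""CSV/JSON dialects for comparison matrices, decision matrices and rankings.

Comparison-matrix CSV: UTF-8, comma separated, '.' decimal; first row is a
header of criterion names, first column repeats them; cells may be decimals
or exact fraction literals like ``1/3``.  JSON alternative:
``{"labels": [...], "entries": [[...]]}``.

Decision-matrix CSV: row 1 criterion names, row 2 directions
(benefit/cost, any case), row 3 weights, then one row per alternative
(label + values).

Floats are written with 12 significant digits so a write/read round trip
is value-identical.
"""

from __future__ import annotations

import csv
import json
import logging
from fractions import Fraction
from pathlib import Path

import numpy as np

from .ahp import PairwiseComparisonMatrix, validate_pcm
from .topsis import (
    BENEFIT,
    COST,
    CriterionSpec,
    DecisionMatrix,
    RankingResult,
    make_decision_matrix,
)

__all__ = [
    "ParseError",
    "read_pcm",
    "write_pcm",
    "read_decision_csv",
    "write_decision_csv",
    "write_ranking",
]

log = logging.getLogger("vinecover")

FLOAT_FMT = "{:.12g}"


class ParseError(ValueError):
    """Malformed input file; message carries row/column coordinates."""


def _parse_cell(text: str, row: int, col: int) -> float:
    text = text.strip()
    try:
        if "/" in text:
            return float(Fraction(text))
        return float(text)
    except (ValueError, ZeroDivisionError) as e:
        raise ParseError(f"row {row}, column {col}: non-numeric cell {text!r}") from e


def read_pcm(path, repair_reciprocity: bool = False) -> PairwiseComparisonMatrix:
    """Read a pairwise comparison matrix from CSV or JSON.

    With ``repair_reciprocity=True`` the lower triangle is reset to exact
    reciprocals of the upper triangle (for CSVs carrying rounded values such
    as 0.33 for 1/3); the repair is logged loudly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        labels = doc["labels"]
        entries = np.asarray(doc["entries"], dtype=float)
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows:
            raise ParseError("empty file")
        labels = [c.strip() for c in rows[0][1:]]
        entries = np.array(
            [
                [_parse_cell(cell, i + 1, j + 1) for j, cell in enumerate(r[1:])]
                for i, r in enumerate(rows[1:])
            ]
        )
    if repair_reciprocity:
        n = entries.shape[0]
        iu = np.triu_indices(n, k=1)
        entries[(iu[1], iu[0])] = 1.0 / entries[iu]
        np.fill_diagonal(entries, 1.0)
        log.warning(
            "repair_reciprocity: lower triangle of %s reset to exact "
            "reciprocals of the upper triangle", path.name,
        )
    return validate_pcm(entries, labels)


def write_pcm(pcm: PairwiseComparisonMatrix, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["criterion", *pcm.labels])
        for lab, row in zip(pcm.labels, pcm.entries):
            w.writerow([lab, *(FLOAT_FMT.format(x) for x in row)])


def read_decision_csv(path) -> DecisionMatrix:
    """Read a decision matrix in the package dialect (see module docstring)."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 5:
        raise ParseError(
            "need header, direction and weight rows plus >= 2 alternatives"
        )
    names = [c.strip() for c in rows[0][1:]]
    if rows[1] and rows[1][0].strip().lower() not in ("direction", ""):
        raise ParseError("row 2 must be the direction row")
    directions = []
    for j, tok in enumerate(rows[1][1:]):
        t = tok.strip().lower()
        if t not in (BENEFIT, COST):
            raise ParseError(
                f"row 2, column {j + 2}: unknown direction token {tok!r} "
                "(expected benefit or cost)"
            )
        directions.append(t)
    weights = [_parse_cell(c, 3, j + 2) for j, c in enumerate(rows[2][1:])]
    if not (len(names) == len(directions) == len(weights)):
        raise ParseError("header, direction and weight rows differ in length")
    labels, values = [], []
    for i, r in enumerate(rows[3:], start=4):
        if not r or all(not c.strip() for c in r):
            continue
        labels.append(r[0].strip())
        values.append([_parse_cell(c, i, j + 2) for j, c in enumerate(r[1:])])
    criteria = tuple(
        CriterionSpec(n, d, w) for n, d, w in zip(names, directions, weights)
    )
    return make_decision_matrix(values, labels, criteria)


def write_decision_csv(dm: DecisionMatrix, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["alternative", *(c.name for c in dm.criteria)])
        w.writerow(["direction", *(c.direction for c in dm.criteria)])
        w.writerow(["weight", *(FLOAT_FMT.format(c.weight) for c in dm.criteria)])
        for lab, row in zip(dm.alternative_labels, dm.values):
            w.writerow([lab, *(FLOAT_FMT.format(x) for x in row)])


def write_ranking(result: RankingResult, path, fmt: str = "csv",
                  sort: str = "rc") -> None:
    """Write a ranking as CSV or JSON, sorted by rc (default) or input order."""
    path = Path(path)
    tab = result.to_frame()
    if sort == "rc":
        tab = tab.sort_values("rank")
    elif sort != "input":
        raise ValueError("sort must be 'rc' or 'input'")
    if fmt == "csv":
        tab.to_csv(path, index_label="alternative", float_format="%.12g")
    elif fmt == "json":
        doc = {
            "ranking": [
                {"alternative": lab, **{k: (int(v) if k == "rank" else float(v))
                                        for k, v in rec.items()}}
                for lab, rec in tab.to_dict(orient="index").items()
            ]
        }
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError("fmt must be 'csv' or 'json'")
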