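"""Readers and writers for the delimited-matrix and gene-set formats.

Matrices are delimited text with one header row (gene/feature IDs) and one
label column (cell-line IDs); the package convention is cell lines as
rows everywhere, with transposition handled at read time.  Gene sets use
the GMT dialect (name, description, members, tab-separated).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SyntheticTruth


class ParseError(ValueError):
    pass


def read_matrix(path: str | Path, orientation: str = "lines_by_genes", sep: str | None = None) -> pd.DataFrame:
    """Read a labelled numeric matrix; empty cells become missing.

    ``orientation`` is the layout of the *file*: ``lines_by_genes`` (rows
    are cell lines) or ``genes_by_lines`` (transposed on read).  Duplicate
    labels or non-numeric payload raise :class:`ParseError` naming the
    offender.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_header = pd.Index(header)
    dup = dup_header[dup_header.duplicated()].unique()
    if len(dup):
        raise ParseError(f"{path}: duplicated column labels: {list(dup)[:5]}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed rows ({exc})") from exc
    for axis, labels in (("row", df.index), ("column", df.columns)):
        dup = labels[labels.duplicated()].unique()
        if len(dup):
            raise ParseError(f"{path}: duplicated {axis} labels: {list(dup)[:5]}")
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        raise ParseError(f"{path}: non-numeric payload in columns {list(bad)[:5]}")
    if orientation == "genes_by_lines":
        df = df.T
    elif orientation != "lines_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name, description, then members, tab-separated."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            uniq = set(members)
            if len(uniq) < len(members):
                warnings.warn(f"{path}:{ln}: duplicate members in {name} deduplicated", stacklevel=2)
            out[name] = uniq
    return out


def write_gene_sets(sets: dict[str, set[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "archetype": truth.archetype,
        "mechanism": truth.mechanism,
        "drug_targets": truth.drug_targets,
        "modules": [sorted(m) for m in truth.modules],
        "dependent_lines": truth.dependent_lines,
        "paralog_partner": truth.paralog_partner,
        "non_expressed": truth.non_expressed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        archetype=d["archetype"],
        mechanism=d["mechanism"],
        drug_targets=d.get("drug_targets", {}),
        modules=[set(m) for m in d.get("modules", [])],
        dependent_lines=d.get("dependent_lines", {}),
        paralog_partner=d.get("paralog_partner", {}),
        non_expressed=d.get("non_expressed", []),
    )
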