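"""Delimited-text readers and writers.

Four formats, all plain text (TSV by default, any single-character
delimiter accepted):

* association edge lists — two columns, miRNA name and disease name;
* MeSH tables — two columns, disease name and dot-delimited tree number;
* labelled square similarity matrices — header row and index column;
* long-format prediction tables — miRNA, disease, score, known flag.

One orientation convention is used everywhere: the association matrix ``Y``
has miRNAs as rows and diseases as columns.  Names are trimmed and matched
case-insensitively but stored as first seen, since curated exports mix
capitalizations of the same heading.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationDataset",
    "MeshTable",
    "read_associations",
    "write_associations",
    "read_mesh_table",
    "write_mesh_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_predictions",
    "read_predictions",
]

#: MeSH-style tree number: a letter-prefixed root followed by dot-separated
#: 3-digit groups, e.g. ``C04.588.945.418``.
TREE_NUMBER_PATTERN = re.compile(r"^[A-Za-z]\d+(?:\.\d{3})*$")


def _norm(name: str) -> str:
    return name.strip().lower()


@dataclass
class AssociationDataset:
    """Named binary miRNA-disease association matrix.

    ``Y[i, j] = 1`` iff miRNA ``mirna_names[i]`` has a recorded association
    with disease ``disease_names[j]``.
    """

    mirna_names: list[str]
    disease_names: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.mirna_names), len(self.disease_names)):
            raise ValueError(
                f"Y shape {self.Y.shape} does not match "
                f"{len(self.mirna_names)} miRNAs x {len(self.disease_names)} diseases"
            )
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        for names, what in ((self.mirna_names, "miRNA"),
                            (self.disease_names, "disease")):
            seen = {_norm(n) for n in names}
            if len(seen) != len(names):
                raise ValueError(f"duplicate {what} names")

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_names)

    @property
    def n_disease(self) -> int:
        return len(self.disease_names)

    @property
    def n_edges(self) -> int:
        return int(self.Y.sum())

    @property
    def density(self) -> float:
        return self.n_edges / (self.n_mirna * self.n_disease)

    def mirna_index(self, name: str) -> int:
        try:
            return self._mirna_lookup[_norm(name)]
        except AttributeError:
            self._mirna_lookup = {_norm(n): i for i, n in enumerate(self.mirna_names)}
            return self._mirna_lookup[_norm(name)]

    def disease_index(self, name: str) -> int:
        try:
            return self._disease_lookup[_norm(name)]
        except AttributeError:
            self._disease_lookup = {
                _norm(n): j for j, n in enumerate(self.disease_names)
            }
            return self._disease_lookup[_norm(name)]

    def known_pairs(self) -> np.ndarray:
        """(n_edges, 2) array of (miRNA index, disease index) for the 1-entries."""
        return np.argwhere(self.Y == 1)


@dataclass
class MeshTable:
    """Disease -> MeSH tree-number table; a disease may occur on several rows."""

    entries: list[tuple[str, str]]
    skipped: int = 0
    _lookup: dict[str, list[str]] = field(default=None, repr=False)  # type: ignore

    def __post_init__(self) -> None:
        lookup: dict[str, list[str]] = {}
        for disease, tn in self.entries:
            lookup.setdefault(_norm(disease), []).append(tn)
        self._lookup = lookup

    def diseases(self) -> list[str]:
        seen, out = set(), []
        for disease, _ in self.entries:
            key = _norm(disease)
            if key not in seen:
                seen.add(key)
                out.append(disease)
        return out

    def tree_numbers(self, disease: str) -> list[str]:
        return list(self._lookup.get(_norm(disease), []))

    def __contains__(self, disease: str) -> bool:
        return _norm(disease) in self._lookup


def _read_rows(path, delimiter: str, header: bool):
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if header and lineno == 1:
                continue
            if not any(f.strip() for f in row):
                continue  # blank line
            rows.append((lineno, row))
    return rows


def read_associations(
    path, delimiter: str = "\t", header: bool = False
) -> AssociationDataset:
    """Read a two-column miRNA/disease edge list into an indexed matrix.

    Rows and columns follow first appearance in the file; duplicate edges
    collapse to a single 1 (the count is logged).  Extra columns beyond the
    first two are ignored.
    """
    rows = _read_rows(path, delimiter, header)
    if not rows:
        raise ValueError(f"{path}: empty association file")
    mirnas: list[str] = []
    diseases: list[str] = []
    m_lookup: dict[str, int] = {}
    d_lookup: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    duplicates = 0
    for lineno, row in rows:
        fields = [f.strip() for f in row]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(
                f"{path}: line {lineno}: expected at least 2 non-empty columns"
            )
        m_name, d_name = fields[0], fields[1]
        mk, dk = _norm(m_name), _norm(d_name)
        if mk not in m_lookup:
            m_lookup[mk] = len(mirnas)
            mirnas.append(m_name)
        if dk not in d_lookup:
            d_lookup[dk] = len(diseases)
            diseases.append(d_name)
        edge = (m_lookup[mk], d_lookup[dk])
        if edge in edges:
            duplicates += 1
        else:
            edges.add(edge)
    if duplicates:
        logger.info("%s: collapsed %d duplicate edges", path, duplicates)
    Y = np.zeros((len(mirnas), len(diseases)))
    for i, j in edges:
        Y[i, j] = 1.0
    return AssociationDataset(mirnas, diseases, Y)


def write_associations(
    dataset: AssociationDataset, path, delimiter: str = "\t"
) -> None:
    """Write the 1-entries of the association matrix as an edge list."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        for i, j in dataset.known_pairs():
            writer.writerow([dataset.mirna_names[i], dataset.disease_names[j]])


def read_mesh_table(path, delimiter: str = "\t", header: bool = False) -> MeshTable:
    """Read a disease -> tree-number table.

    Rows with malformed tree numbers are skipped with a warning; the skip
    count is kept on the returned table.  Multiplicity of tree numbers per
    disease is preserved.
    """
    rows = _read_rows(path, delimiter, header)
    if not rows:
        raise ValueError(f"{path}: empty MeSH table")
    entries: list[tuple[str, str]] = []
    stored: dict[str, str] = {}
    skipped = 0
    for lineno, row in rows:
        fields = [f.strip() for f in row]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 non-empty columns"
            )
        disease, tn = fields[0], fields[1]
        if not TREE_NUMBER_PATTERN.match(tn):
            logger.warning(
                "%s: line %d: malformed tree number %r skipped", path, lineno, tn
            )
            skipped += 1
            continue
        key = _norm(disease)
        stored.setdefault(key, disease)
        entries.append((stored[key], tn))
    return MeshTable(entries, skipped=skipped)


def write_mesh_table(table: MeshTable, path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerows(table.entries)


def read_similarity_matrix(path, delimiter: str = "\t") -> SimilarityMatrix:
    """Read a labelled square similarity matrix.

    The matrix is symmetrized by averaging (asymmetry beyond 1e-8 is logged)
    and values are clipped to [0, 1] with a logged clip count.  Entries are
    flagged as primary (curated) similarity.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    row_labels = [str(l).strip() for l in df.index]
    col_labels = [str(l).strip() for l in df.columns]
    if len(row_labels) != len(col_labels):
        raise ValueError(f"{path}: similarity matrix is not square")
    if [_norm(a) for a in row_labels] != [_norm(b) for b in col_labels]:
        raise ValueError(f"{path}: row and column labels do not match")
    M = df.to_numpy(dtype=float)
    asym = float(np.abs(M - M.T).max()) if M.size else 0.0
    if asym > 1e-8:
        logger.warning("%s: asymmetry up to %.3g; symmetrizing by averaging",
                       path, asym)
    M = (M + M.T) / 2.0
    n_clip = int(((M < 0) | (M > 1)).sum())
    if n_clip:
        logger.warning("%s: clipped %d entries to [0, 1]", path, n_clip)
        M = np.clip(M, 0.0, 1.0)
    return SimilarityMatrix(
        row_labels, M, primary_mask=np.ones((len(row_labels),) * 2, dtype=bool)
    )


def write_similarity_matrix(
    sim: SimilarityMatrix, path, delimiter: str = "\t"
) -> None:
    df = pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def write_predictions(
    ystar: np.ndarray,
    dataset: AssociationDataset,
    path,
    delimiter: str = "\t",
) -> None:
    """Write the score matrix as a long table, one row per (miRNA, disease).

    Within each disease (diseases in dataset column order) rows are sorted
    by score descending, ties broken by miRNA index ascending.  Scores are
    written with 17 significant digits so a round trip is lossless.
    """
    ystar = np.asarray(ystar, dtype=float)
    if ystar.shape != dataset.Y.shape:
        raise ValueError("score matrix shape does not match dataset")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["miRNA", "disease", "score", "known"])
        for j, disease in enumerate(dataset.disease_names):
            order = np.lexsort((np.arange(dataset.n_mirna), -ystar[:, j]))
            for i in order:
                writer.writerow([
                    dataset.mirna_names[i],
                    disease,
                    format(ystar[i, j], ".17g"),
                    int(dataset.Y[i, j]),
                ])


def read_predictions(path, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    expected = ["miRNA", "disease", "score", "known"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    return df
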