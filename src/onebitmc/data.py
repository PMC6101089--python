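"""Readers and writers for binary association data.

Two on-disk dialects are supported:

* a *long* format — one ``(microbe_id, disease_id, label)`` record per line,
  TSV or CSV, with an optional label column defaulting to ``+1``;
* a *dense* format — a TSV matrix with disease ids in the header row,
  microbe ids in the first column, and cells in ``{1, -1, NA/empty}``.

Internally an association table is an :class:`ObservedMatrix`: a p x q grid
whose entries are +1 (association), -1 (observed non-association) or unknown,
together with the set of observed positions (Omega).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObservedMatrix",
    "AssociationRecord",
    "read_association_list",
    "read_dense_matrix",
    "write_dense_matrix",
    "write_score_table",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One observed pair: ``label`` is strictly +1 or -1."""

    microbe_id: str
    disease_id: str
    label: int = 1

    def __post_init__(self) -> None:
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label!r}")


@dataclass
class ObservedMatrix:
    """A p x q binary adjacency with entries in {+1, -1, unknown}.

    ``values`` holds the labels as int8 with 0 at unknown cells; ``observed``
    is the boolean mask of Omega. Both invariants — values are nonzero exactly
    on Omega, ids are unique — are checked at construction.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.observed is None:
            self.observed = self.values != 0
        self.observed = np.asarray(self.observed, dtype=bool)
        p, q = self.values.shape
        if len(self.row_ids) != p or len(self.col_ids) != q:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.row_ids)) != p:
            raise ValueError("duplicate row (microbe) identifiers")
        if len(set(self.col_ids)) != q:
            raise ValueError("duplicate column (disease) identifiers")
        if self.observed.shape != (p, q):
            raise ValueError("observed mask shape mismatch")
        obs_vals = self.values[self.observed]
        if not np.all(np.isin(obs_vals, (1, -1))):
            raise ValueError("observed entries must be +1 or -1")
        if np.any(self.values[~self.observed] != 0):
            raise ValueError("unobserved entries must be unknown (0)")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def m(self) -> int:
        """|Omega|, the number of observed entries."""
        return int(self.observed.sum())

    @property
    def omega(self) -> set[tuple[int, int]]:
        """Observed index pairs as a set of (row, col)."""
        rr, cc = np.nonzero(self.observed)
        return set(zip(rr.tolist(), cc.tolist()))

    def omega_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Observed positions as parallel (rows, cols) index arrays."""
        return np.nonzero(self.observed)

    def mask_entries(self, rows: np.ndarray, cols: np.ndarray) -> "ObservedMatrix":
        """Return a copy with the given entries blinded (removed from Omega)."""
        values = self.values.copy()
        observed = self.observed.copy()
        values[rows, cols] = 0
        observed[rows, cols] = False
        return ObservedMatrix(list(self.row_ids), list(self.col_ids), values, observed)

    def to_records(self) -> list[AssociationRecord]:
        """Serialize the observed entries back to a pair list (lossless)."""
        rr, cc = self.omega_indices()
        return [
            AssociationRecord(self.row_ids[i], self.col_ids[j], int(self.values[i, j]))
            for i, j in zip(rr.tolist(), cc.tolist())
        ]


_LABEL_TOKENS = {"1": 1, "+1": 1, "-1": -1}


def _parse_label(token: str, line_no: int) -> int:
    token = token.strip()
    if token not in _LABEL_TOKENS:
        raise ValueError(
            f"line {line_no}: malformed label {token!r} (accepted: 1, +1, -1; "
            "0 is ambiguous between negative and unknown and is refused)"
        )
    return _LABEL_TOKENS[token]


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_association_list(path, unknown_policy: str = "as_negative") -> ObservedMatrix:
    """Build an ObservedMatrix from a long-format pair list.

    Parameters
    ----------
    path
        TSV/CSV file with header ``microbe_id, disease_id[, label]``.
    unknown_policy
        ``"as_negative"`` marks every unlisted pair as an observed -1 (Omega
        covers all p*q cells); ``"as_missing"`` leaves unlisted pairs unknown.
        Source databases typically record only positives, so the negatives
        have to come from a policy; it is explicit here rather than implied.
    """
    if unknown_policy not in ("as_negative", "as_missing"):
        raise ValueError(f"unknown_policy must be as_negative/as_missing, got {unknown_policy!r}")
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    header = next(reader)
    header = [h.strip().lower() for h in header]
    if header[:2] != ["microbe_id", "disease_id"]:
        raise ValueError(
            f"{path}: header must start with 'microbe_id', 'disease_id' (got {header!r})"
        )
    has_label = len(header) >= 3 and header[2] == "label"

    row_ids: list[str] = []
    col_ids: list[str] = []
    row_index: dict[str, int] = {}
    col_index: dict[str, int] = {}
    seen: dict[tuple[int, int], int] = {}
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise ValueError(f"{path}: line {line_no}: expected at least 2 fields")
        mid, did = row[0].strip(), row[1].strip()
        label = _parse_label(row[2], line_no) if has_label and len(row) > 2 and row[2].strip() else 1
        if mid not in row_index:
            row_index[mid] = len(row_ids)
            row_ids.append(mid)
        if did not in col_index:
            col_index[did] = len(col_ids)
            col_ids.append(did)
        key = (row_index[mid], col_index[did])
        if key in seen:
            if seen[key] != label:
                raise ValueError(
                    f"{path}: line {line_no}: conflicting labels for pair ({mid}, {did})"
                )
            continue
        seen[key] = label
    if not seen:
        raise ValueError(f"{path}: no association records found")

    p, q = len(row_ids), len(col_ids)
    if unknown_policy == "as_negative":
        values = np.full((p, q), -1, dtype=np.int8)
    else:
        values = np.zeros((p, q), dtype=np.int8)
    for (i, j), label in seen.items():
        values[i, j] = label
    return ObservedMatrix(row_ids, col_ids, values)


_DENSE_TOKENS = {"1": 1, "+1": 1, "-1": -1, "NA": 0, "": 0}


def read_dense_matrix(path) -> ObservedMatrix:
    """Read the dense TSV dialect (header row = disease ids, first column =
    microbe ids, cells in {1, -1, NA/empty})."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise ValueError(f"{path}: no data rows")
    header = rows[0]
    col_ids = [c.strip() for c in header[1:]]
    if not col_ids:
        raise ValueError(f"{path}: no data columns")
    q = len(col_ids)
    row_ids: list[str] = []
    values = np.zeros((len(rows) - 1, q), dtype=np.int8)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != q + 1:
            raise ValueError(f"{path}: line {i}: ragged row ({len(row)} fields, expected {q + 1})")
        row_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            token = cell.strip()
            if token not in _DENSE_TOKENS:
                raise ValueError(
                    f"{path}: line {i}: cell {token!r} not in {{1, -1, NA, empty}}"
                )
            values[i - 2, j] = _DENSE_TOKENS[token]
    return ObservedMatrix(row_ids, col_ids, values)


def write_dense_matrix(observed: ObservedMatrix, path) -> None:
    """Write the dense TSV dialect; unknown cells are written as ``NA``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([""] + list(observed.col_ids))
        for i, rid in enumerate(observed.row_ids):
            cells = [
                str(int(observed.values[i, j])) if observed.observed[i, j] else "NA"
                for j in range(observed.q)
            ]
            writer.writerow([rid] + cells)


def write_score_table(
    X: np.ndarray,
    observed: ObservedMatrix,
    path,
    top_k: int | None = None,
) -> None:
    """Write a ranked candidate table: ``microbe_id  disease_id  score
    observed``, sorted by score descending, ties broken by (row, col) index
    ascending. Scores are printed at 6 significant digits."""
    X = np.asarray(X, dtype=float)
    if X.shape != observed.shape:
        raise ValueError(f"score matrix shape {X.shape} != data shape {observed.shape}")
    p, q = X.shape
    flat = X.ravel()
    # stable sort on -score keeps (i, j) ascending among ties
    order = np.argsort(-flat, kind="stable")
    if top_k is not None:
        order = order[: max(0, int(top_k))]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["microbe_id", "disease_id", "score", "observed"])
        for idx in order:
            i, j = divmod(int(idx), q)
            writer.writerow(
                [
                    observed.row_ids[i],
                    observed.col_ids[j],
                    f"{flat[idx]:.6g}",
                    "1" if observed.observed[i, j] else "0",
                ]
            )
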