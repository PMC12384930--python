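"""Reading, cleaning, encoding and splitting CAP Sleep Database-style annotation files.

The annotation dialect is a UTF-8 text file with free-form preamble lines,
a tab-separated header line containing ``Sleep Stage``, and one tab-separated
event row per line.  Canonical columns after cleaning are ``Sleep Stage``,
``Position``, ``Time [hh:mm:ss]``, ``Event``, ``Duration[s]`` and ``Location``.
Files that lack a ``Position`` column get a placeholder inserted before
renaming so every cleaned table has the same six columns.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = [
    "Sleep Stage",
    "Position",
    "Time [hh:mm:ss]",
    "Event",
    "Duration[s]",
    "Location",
]

#: Columns that are integer-encoded for model input; Event stays categorical
#: because it is the classification target.
ENCODED_COLUMNS = ["Sleep Stage", "Position", "Location"]


class AnnotationParseError(ValueError):
    """Raised when a file has no 'Sleep Stage' header line."""


class EmptyTableError(ValueError):
    """Raised when cleaning leaves zero usable rows."""


@dataclass
class AnnotationTable:
    """Cleaned per-event annotation rows for one patient.

    ``frame`` preserves file order and always carries the six canonical
    columns; every ``Duration[s]`` value is finite and positive.
    """

    frame: pd.DataFrame
    patient_id: str = ""

    def __post_init__(self) -> None:
        if list(self.frame.columns) != CANONICAL_COLUMNS:
            raise ValueError(
                f"expected columns {CANONICAL_COLUMNS}, got {list(self.frame.columns)}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        if self.patient_id != other.patient_id or len(self) != len(other):
            return False
        a, b = self.frame.reset_index(drop=True), other.frame.reset_index(drop=True)
        for col in CANONICAL_COLUMNS:
            if col == "Duration[s]":
                if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float)):
                    return False
            elif not (a[col].astype(str) == b[col].astype(str)).all():
                return False
        return True


@dataclass
class LabelEncoding:
    """Invertible categorical→integer maps for the encoded columns.

    Codes are contiguous ``0..K-1`` over lexicographically sorted labels, so
    the assignment is deterministic and independent of row order.
    """

    maps: dict[str, dict[str, int]] = field(default_factory=dict)

    def encode(self, column: str, label: str) -> int:
        return self.maps[column][str(label)]

    def decode(self, column: str, code: int) -> str:
        inverse = {v: k for k, v in self.maps[column].items()}
        return inverse[int(code)]


def read_annotation_file(text: str, patient_id: str = "") -> AnnotationTable:
    """Parse raw annotation-file contents into a cleaned :class:`AnnotationTable`.

    Data begins after the first line containing ``Sleep Stage``; rows are split
    on tabs.  Five-column files (no Position) get a placeholder inserted at
    index 1; extra trailing columns beyond six are dropped with a warning.
    Rows with any missing field or a non-numeric/non-positive duration are
    removed.
    """
    if not text:
        raise AnnotationParseError("empty annotation text")
    lines = text.splitlines()
    header_idx = next((i for i, ln in enumerate(lines) if "Sleep Stage" in ln), None)
    if header_idx is None:
        raise AnnotationParseError("no 'Sleep Stage' header line found")

    header = lines[header_idx].split("\t")
    has_position = any("Position" in h for h in header)
    data_lines = [ln for ln in lines[header_idx + 1 :] if ln.strip()]
    rows = [ln.split("\t") for ln in data_lines]

    expected = 6 if has_position else 5
    parsed = []
    for cells in rows:
        if len(cells) > expected:
            warnings.warn(
                f"dropping {len(cells) - expected} extra column(s) in a row",
                stacklevel=2,
            )
            cells = cells[:expected]
        elif len(cells) < expected:
            cells = cells + [""] * (expected - len(cells))
        if not has_position:
            # sentinel, not a missing value: position is legitimately absent
            # in 5-column files and must survive the missing-row purge
            cells = [cells[0], "n/a"] + cells[1:]
        parsed.append(cells)

    frame = pd.DataFrame(parsed, columns=CANONICAL_COLUMNS)
    frame = frame.replace("", np.nan).dropna()
    frame["Duration[s]"] = pd.to_numeric(frame["Duration[s]"], errors="coerce")
    frame = frame.dropna()
    frame = frame[np.isfinite(frame["Duration[s]"]) & (frame["Duration[s]"] > 0)]
    frame = frame.reset_index(drop=True)
    if len(frame) == 0:
        raise EmptyTableError(f"no usable annotation rows (patient {patient_id!r})")
    return AnnotationTable(frame=frame, patient_id=patient_id)


def write_annotation_file(table: AnnotationTable) -> str:
    """Serialize a table back to the tab-separated dialect (round-trippable)."""
    buf = io.StringIO()
    buf.write(f"Patient: {table.patient_id}\n")
    buf.write("\t".join(CANONICAL_COLUMNS) + "\n")
    for _, row in table.frame.iterrows():
        dur = row["Duration[s]"]
        dur_str = repr(float(dur))
        cells = [
            str(row["Sleep Stage"]),
            str(row["Position"]),
            str(row["Time [hh:mm:ss]"]),
            str(row["Event"]),
            dur_str,
            str(row["Location"]),
        ]
        buf.write("\t".join(cells) + "\n")
    return buf.getvalue()


def encode_labels(
    table: AnnotationTable, encoding: LabelEncoding | None = None
) -> tuple[pd.DataFrame, LabelEncoding]:
    """Integer-code Sleep Stage, Position and Location; Event is untouched.

    When ``encoding`` is given (e.g. fit on the training split), it is applied
    as-is; otherwise a fresh encoding is fit on this table's sorted unique
    labels.
    """
    if encoding is None:
        encoding = LabelEncoding(
            maps={
                col: {
                    lab: i
                    for i, lab in enumerate(sorted(table.frame[col].astype(str).unique()))
                }
                for col in ENCODED_COLUMNS
            }
        )
    encoded = table.frame.copy()
    for col in ENCODED_COLUMNS:
        encoded[col] = [encoding.maps[col][str(v)] for v in encoded[col]]
    return encoded, encoding


def patient_split(
    tables: dict[str, AnnotationTable],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[set[str], set[str], set[str]]:
    """Split patient ids into disjoint train/val/test sets.

    Splitting is at the patient level so no patient's rows ever appear in two
    sets; reproducible under ``seed``.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 patients to split")
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    ids = sorted(tables)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = max(1, min(n_train, n - 2))
    n_val = max(1, min(n_val, n - n_train - 1))
    train = set(ids[:n_train])
    val = set(ids[n_train : n_train + n_val])
    test = set(ids[n_train + n_val :])
    return train, val, test
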