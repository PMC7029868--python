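"""Readers and writers for the documented skeleton and feature-matrix dialects.

Skeleton dialect
----------------
CSV (default) or JSONL with one record per (hand, frame):

``subject_id,sign_label,repetition,hand,frame,EF1_x,EF1_y,EF1_z,...,PALM_z``

Coordinates are millimetres in the sensor frame, stored as decimal text with
6 significant digits (sub-millimetre sensor accuracy makes this lossless in
practice).  Frames of one (subject, sign, repetition, hand) group must appear
with strictly increasing frame indices.

Feature-matrix dialect
----------------------
CSV with ``#``-prefixed metadata header lines (subject_id, sign_label, groups,
shape, optional role), then a standard header row of the 60 column names and
one row per frame, stored at full float precision.
"""

from __future__ import annotations

import io
import json
import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .containers import (
    FeatureMatrix,
    HANDS,
    LANDMARK_NAMES,
    N_LANDMARKS,
    SignRecording,
    SkeletonSequence,
)
from .errors import DialectError

COORD_COLUMNS = tuple(
    f"{name}_{axis}" for name in LANDMARK_NAMES for axis in ("x", "y", "z")
)
META_COLUMNS = ("subject_id", "sign_label", "repetition", "hand", "frame")
ALL_COLUMNS = META_COLUMNS + COORD_COLUMNS

#: decimal significant digits used when writing coordinates
COORD_PRECISION = 6


def _format_coord(x: float) -> str:
    return f"{x:.{COORD_PRECISION}g}"


def _detect_dialect(path: str, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "jsonl"):
            raise DialectError(f"unknown dialect {dialect!r}")
        return dialect
    return "jsonl" if str(path).endswith((".jsonl", ".ndjson")) else "csv"


def _frame_table(path: str, dialect: str) -> pd.DataFrame:
    if dialect == "csv":
        table = pd.read_csv(path, dtype={"subject_id": str, "sign_label": str})
    else:
        records = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise DialectError(f"line {lineno}: invalid JSON: {exc}") from exc
        table = pd.DataFrame.from_records(records)
        if table.empty:
            table = pd.DataFrame(columns=ALL_COLUMNS)
    missing = [c for c in ALL_COLUMNS if c not in table.columns]
    if missing:
        raise DialectError(f"file is missing required columns: {missing[:5]}")
    return table


def read_recordings(path: str, dialect: Optional[str] = None) -> list[SignRecording]:
    """Read all sign recordings from a skeleton file.

    Returns one :class:`SignRecording` per (subject, sign, repetition) group,
    frames ordered by frame index.  Raises :class:`DialectError` naming the
    first offending record on any dialect violation.
    """
    dialect = _detect_dialect(path, dialect)
    table = _frame_table(path, dialect)
    recordings = []
    group_keys = ["subject_id", "sign_label", "repetition"]
    for (subject, sign, repetition), group in table.groupby(group_keys, sort=True):
        hands = {}
        for hand, hand_rows in group.groupby("hand", sort=True):
            if hand not in HANDS:
                raise DialectError(
                    f"recording ({subject}, {sign}, rep {repetition}): "
                    f"invalid hand {hand!r}"
                )
            frames = hand_rows["frame"].to_numpy()
            if not np.all(np.diff(frames) > 0):
                raise DialectError(
                    f"recording ({subject}, {sign}, rep {repetition}, {hand}): "
                    "frame indices are not strictly increasing"
                )
            coords = hand_rows[list(COORD_COLUMNS)].to_numpy(dtype=float)
            bad = np.argwhere(~np.isfinite(coords))
            if bad.size:
                row, col = bad[0]
                landmark = COORD_COLUMNS[col].rsplit("_", 1)[0]
                raise DialectError(
                    f"recording ({subject}, {sign}, rep {repetition}, {hand}): "
                    f"frame {frames[row]} is missing landmark {landmark}"
                )
            hands[hand] = SkeletonSequence(
                subject_id=str(subject),
                sign_label=str(sign),
                hand=str(hand),
                positions=coords.reshape(-1, N_LANDMARKS, 3),
            )
        for hand in HANDS:
            if hand not in hands:
                raise DialectError(
                    f"recording ({subject}, {sign}, rep {repetition}): "
                    f"missing {hand} hand"
                )
        recordings.append(
            SignRecording(
                subject_id=str(subject),
                sign_label=str(sign),
                repetition=int(repetition),
                left=hands["left"],
                right=hands["right"],
            )
        )
    return recordings


def _recording_rows(recording: SignRecording) -> Iterable[dict]:
    for hand in HANDS:
        seq = getattr(recording, hand)
        for t in range(seq.n_frames):
            row = {
                "subject_id": recording.subject_id,
                "sign_label": recording.sign_label,
                "repetition": recording.repetition,
                "hand": hand,
                "frame": t,
            }
            flat = seq.positions[t].reshape(-1)
            row.update(
                {col: _format_coord(v) for col, v in zip(COORD_COLUMNS, flat)}
            )
            yield row


def write_recordings(
    recordings: Iterable[SignRecording], path: str, dialect: Optional[str] = None
) -> None:
    """Write recordings to ``path`` in the documented dialect.

    The output re-reads to identical content; writing what was just read
    produces a byte-identical file.
    """
    dialect = _detect_dialect(path, dialect)
    rows = [row for rec in recordings for row in _recording_rows(rec)]
    if dialect == "csv":
        buffer = io.StringIO()
        buffer.write(",".join(ALL_COLUMNS) + "\n")
        for row in rows:
            buffer.write(",".join(str(row[c]) for c in ALL_COLUMNS) + "\n")
        text = buffer.getvalue()
    else:
        lines = []
        for row in rows:
            typed = {k: row[k] for k in META_COLUMNS}
            typed.update({c: float(row[c]) for c in COORD_COLUMNS})
            lines.append(json.dumps(typed))
        text = "\n".join(lines) + ("\n" if lines else "")
    with open(path, "w") as handle:
        handle.write(text)


def write_feature_matrix(matrix: FeatureMatrix, path: str) -> None:
    """Write a feature matrix losslessly, refusing non-finite values."""
    if not np.all(np.isfinite(matrix.values)):
        raise DialectError("feature matrix contains non-finite values; refusing")
    m, n = matrix.values.shape
    with open(path, "w") as handle:
        handle.write(f"# subject_id: {matrix.subject_id}\n")
        handle.write(f"# sign_label: {matrix.sign_label}\n")
        if matrix.role is not None:
            handle.write(f"# role: {matrix.role}\n")
        handle.write(f"# shape: {m}x{n}\n")
        handle.write("# groups: " + ",".join(matrix.groups) + "\n")
        handle.write(",".join(matrix.columns) + "\n")
        for row in matrix.values:
            handle.write(",".join(f"{v:.17g}" for v in row) + "\n")


def read_feature_matrix(path: str) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    meta: dict[str, str] = {}
    with open(path) as handle:
        lines = handle.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].partition(":")
        meta[key.strip()] = value.strip()
    if "shape" not in meta or "groups" not in meta:
        raise DialectError("feature file lacks '# shape' / '# groups' headers")
    m, n = (int(v) for v in meta["shape"].split("x"))
    table = pd.read_csv(
        io.StringIO("".join(lines[body_start:])), float_precision="round_trip"
    )
    values = table.to_numpy(dtype=float)
    if values.shape != (m, n):
        raise DialectError(
            f"feature file declares shape {m}x{n} but contains {values.shape}"
        )
    groups = tuple(meta["groups"].split(","))
    return FeatureMatrix(
        values=values,
        columns=tuple(table.columns),
        groups=groups,
        subject_id=meta.get("subject_id", ""),
        sign_label=meta.get("sign_label", ""),
        role=meta.get("role"),
    )


def validate_file(path: str, dialect: Optional[str] = None) -> int:
    """Validate a skeleton file; return the number of recordings it holds."""
    if not os.path.exists(path):
        raise DialectError(f"no such file: {path}")
    return len(read_recordings(path, dialect=dialect))
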