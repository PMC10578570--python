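"""CSV reading/writing and run manifests.

All tables are plain UTF-8 CSV with a header row.  Undefined values are
written as empty fields; on read, empty strings and the tokens ``NA`` /
``NaN`` (case-insensitive) are treated as missing.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .responses import ResponseMatrix
from .scorer import SCORE_COLUMNS

__all__ = [
    "ResponseParseError",
    "read_responses_csv",
    "write_responses_csv",
    "write_scores_csv",
    "write_metrics_csv",
    "write_manifest",
]

MISSING_TOKENS = {"", "na", "nan"}


class ResponseParseError(ValueError):
    pass


def read_responses_csv(path: str | Path) -> ResponseMatrix:
    """Read a wide ternary response table.

    Expected header: ``respondent_id`` then ``item_1 .. item_n``.  Cells
    must be 0, 1 or a missing token; anything else raises
    :class:`ResponseParseError` naming the offending cell.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ResponseParseError(f"{path}: empty file") from None
        if not header or header[0] != "respondent_id":
            raise ResponseParseError(
                f"{path}: first column must be 'respondent_id', got "
                f"{header[0] if header else '<none>'!r}"
            )
        expected = [f"item_{j}" for j in range(1, len(header))]
        if header[1:] != expected:
            raise ResponseParseError(
                f"{path}: item columns must be item_1..item_{len(header) - 1} "
                f"in order"
            )
        n_items = len(header) - 1
        if n_items == 0:
            raise ResponseParseError(f"{path}: no item columns")

        ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != n_items + 1:
                raise ResponseParseError(
                    f"{path}, line {lineno}: expected {n_items + 1} fields, "
                    f"got {len(rec)}"
                )
            rid = rec[0]
            if rid in seen:
                raise ResponseParseError(
                    f"{path}, line {lineno}: duplicate respondent_id {rid!r}"
                )
            seen.add(rid)
            row: list[float] = []
            for j, cell in enumerate(rec[1:], start=1):
                token = cell.strip()
                if token.lower() in MISSING_TOKENS:
                    row.append(float("nan"))
                elif token in ("0", "1"):
                    row.append(float(token))
                elif token in ("0.0", "1.0"):
                    row.append(float(token))
                else:
                    raise ResponseParseError(
                        f"{path}, line {lineno}, column item_{j}: invalid "
                        f"response {cell!r} (expected 0, 1 or missing)"
                    )
            ids.append(rid)
            rows.append(row)

    values = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, n_items), dtype=float)
    )
    return ResponseMatrix(ids=tuple(ids), values=values)


def write_responses_csv(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix; missing cells become empty fields."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["respondent_id"] + [f"item_{j + 1}" for j in range(matrix.n_items)]
        )
        for rid, row in zip(matrix.ids, matrix.values):
            writer.writerow(
                [rid] + ["" if np.isnan(v) else str(int(v)) for v in row]
            )


def _write_frame(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def write_scores_csv(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort score table in the documented column order."""
    _write_frame(scores[SCORE_COLUMNS], path)


def write_metrics_csv(metrics: pd.DataFrame, path: str | Path) -> None:
    _write_frame(metrics, path)


def write_manifest(
    path: str | Path, seed: Optional[int], config: dict
) -> None:
    """Deterministic run manifest (seed, package versions, config hash)."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "mcqkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
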