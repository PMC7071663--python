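"""CSV/JSON readers and writers.

All tabular interfaces are plain UTF-8 CSV (BOM tolerated, comma delimiter,
``.`` decimal point).  Pairwise-comparison files additionally accept Saaty
style fraction judgments (``1/3``), which are parsed exactly as rationals
before conversion.  Output files carry a ``#``-prefixed provenance header
(tool version, seed, config hash) that readers here skip transparently; the
header contains no timestamps, so identical runs produce identical bytes.
"""

from __future__ import annotations

import csv
import hashlib
import json
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ahp import ConsistencyReport, PairwiseMatrix

__all__ = [
    "TableError",
    "read_table",
    "parse_judgment",
    "read_pairwise_csv",
    "write_pairwise_csv",
    "provenance_lines",
    "config_hash",
    "write_frame_csv",
    "read_frame_csv",
    "write_json",
    "read_json",
    "write_weights_json",
]


class TableError(ValueError):
    """Malformed tabular input."""


def read_table(
    path: Union[str, Path],
    required: Sequence[str],
    numeric: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a CSV with a required (order-insensitive) set of columns.

    Columns in ``numeric`` are converted to floats; a cell that fails to
    parse is reported with its row number.  UTF-8 BOMs and ``#`` comment
    lines are tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise TableError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype=str, encoding="utf-8-sig", comment="#")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        values = []
        for i, cell in enumerate(frame[col]):
            try:
                values.append(float(cell))
            except (TypeError, ValueError):
                raise TableError(
                    f"{path}: unparseable value {cell!r} in column "
                    f"{col!r}, row {i + 2}"
                ) from None
        frame[col] = values
    return frame


def parse_judgment(text: str) -> Union[Fraction, float]:
    """Parse one pairwise-comparison cell.

    ``"1/3"`` becomes the exact rational one-third (so ``3 * parse("1/3")
    == 1`` holds identically); plain decimals become floats.
    """
    cell = str(text).strip()
    if not cell:
        raise TableError("empty judgment cell")
    if "/" in cell:
        num, _, den = cell.partition("/")
        try:
            return Fraction(int(num.strip()), int(den.strip()))
        except (ValueError, ZeroDivisionError) as exc:
            raise TableError(f"bad fraction judgment {cell!r}") from exc
    try:
        return float(cell)
    except ValueError:
        raise TableError(f"bad judgment {cell!r}") from None


def read_pairwise_csv(path: Union[str, Path]) -> PairwiseMatrix:
    """Read a pairwise matrix: a header row of criterion labels, then n
    rows of n judgments (decimals or ``a/b`` fractions)."""
    path = Path(path)
    if not path.exists():
        raise TableError(f"no such file: {path}")
    with path.open("r", encoding="utf-8-sig", newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise TableError(f"{path}: empty pairwise file")
    labels = tuple(c.strip() for c in rows[0])
    n = len(labels)
    if len(rows) - 1 != n:
        raise TableError(
            f"{path}: expected {n} judgment rows for {n} labels, "
            f"got {len(rows) - 1}"
        )
    values = np.empty((n, n))
    for i, row in enumerate(rows[1:]):
        if len(row) != n:
            raise TableError(f"{path}: row {i + 2} has {len(row)} cells, not {n}")
        for j, cell in enumerate(row):
            values[i, j] = float(parse_judgment(cell))
    return PairwiseMatrix(values, labels)


def write_pairwise_csv(
    matrix: PairwiseMatrix, path: Union[str, Path], header: Sequence[str] = ()
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(matrix.labels)
        for row in matrix.values:
            writer.writerow([repr(float(v)) for v in row])


# --------------------------------------------------------------------------
# Provenance
# --------------------------------------------------------------------------

def _version() -> str:
    from . import __version__

    return __version__


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: Optional[int] = None,
                     cfg_hash: Optional[str] = None) -> list[str]:
    parts = [f"prioritycompass {_version()}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return [" ".join(parts)]


def provenance_dict(seed: Optional[int] = None,
                    cfg_hash: Optional[str] = None) -> dict:
    out = {"tool": "prioritycompass", "version": _version()}
    if seed is not None:
        out["seed"] = seed
    if cfg_hash is not None:
        out["config"] = cfg_hash
    return out


def write_frame_csv(
    frame: pd.DataFrame,
    path: Union[str, Path],
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
    index: bool = False,
) -> None:
    """Write a DataFrame as CSV under a provenance comment header.

    Floats are written with ``repr`` round-trip precision so a write->read
    cycle preserves every value exactly.
    """
    path = Path(path)
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(repr)  # shortest round-trip repr
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in provenance_lines(seed, cfg_hash):
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=index, lineterminator="\n")


def read_frame_csv(path: Union[str, Path], **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, comment="#", encoding="utf-8-sig",
        float_precision="round_trip", **kwargs,
    )


def write_json(
    payload: Mapping,
    path: Union[str, Path],
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    body = {"provenance": provenance_dict(seed, cfg_hash)}
    body.update(payload)
    Path(path).write_text(
        json.dumps(body, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_json(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_weights_json(
    weights: pd.Series,
    report: ConsistencyReport,
    path: Union[str, Path],
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    write_json(
        {
            "weights": {str(k): float(v) for k, v in weights.items()},
            "consistency": report.to_dict(),
        },
        path,
        seed=seed,
        cfg_hash=cfg_hash,
    )
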