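"""Reading time series from text files and writing analysis reports."""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .ordinal import SeriesTooShortError
from .surrogates import TimeSeries
from .uncertainty import UncertaintyResult

__all__ = ["read_series", "write_report", "read_report"]


class ParseError(ValueError):
    """A token in the input file could not be parsed as a finite number."""


def read_series(
    path: Union[str, Path], column: Optional[Union[str, int]] = None
) -> TimeSeries:
    """Read a scalar time series from a plain-text or delimited file.

    With ``column=None`` the file must hold one value per line; lines that
    are blank or start with ``#`` are skipped, and a bad token raises
    :class:`ParseError` naming the offending line.  With a ``column``
    (name or zero-based index) the file is parsed as delimited text with
    the separator sniffed automatically, and that column is returned in
    file order.
    """
    path = Path(path)
    if column is None:
        values = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: cannot parse {token!r} as a number; "
                    "pass a column selector for delimited files"
                ) from None
        if len(values) < 2:
            raise SeriesTooShortError(
                f"{path}: found {len(values)} samples, need at least 2"
            )
        return TimeSeries(values, label=path.name)
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    if isinstance(column, int):
        if not 0 <= column < frame.shape[1]:
            raise ParseError(f"{path}: no column index {column}")
        series = frame.iloc[:, column]
    else:
        if column not in frame.columns:
            raise ParseError(
                f"{path}: no column {column!r}; available: {list(frame.columns)}"
            )
        series = frame[column]
    values = pd.to_numeric(series, errors="raise").to_numpy(dtype=float)
    if values.size < 2:
        raise SeriesTooShortError(f"{path}: found {values.size} samples, need >= 2")
    return TimeSeries(values, label=f"{path.name}:{column}")


def write_report(result: UncertaintyResult, path: Union[str, Path]) -> None:
    """Serialize an :class:`UncertaintyResult` to a JSON report.

    Every numerical field round-trips bit-exactly (JSON floats are written
    with shortest-repr precision); the wall-clock timestamp lives in a
    separate ``meta`` field so two runs of the same analysis produce
    reports that are identical outside ``meta``.
    """
    est = result.estimate
    payload = {
        "h": est.h,
        "h_normalized": est.h_normalized,
        "plug_in": est.plug_in,
        "mm_correction": est.mm_correction,
        "sigma": est.sigma,
        "sigma_label": est.sigma_label,
        "s_surrogate": result.s_surrogate,
        "alpha": result.alpha,
        "l": result.l,
        "m": est.m,
        "n": est.n,
        "seed": result.seed,
        "max_iter": result.max_iter,
        "mean_surrogate_pe": result.mean_surrogate_pe,
        "per_surrogate_pe": list(result.per_surrogate_pe),
        "converged": list(result.converged),
        "iterations": list(result.iterations),
        "meta": {"written_at": time.strftime("%Y-%m-%dT%H:%M:%S%z")},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: Union[str, Path]) -> dict:
    """Load a report written by :func:`write_report` as a plain dictionary."""
    return json.loads(Path(path).read_text())
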