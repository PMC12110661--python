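"""Plain-text series I/O: one value per line, or single-column CSV with header."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_series", "write_series"]


def read_series(path) -> np.ndarray:
    """Read a series from plain text (one value per line).

    A single-column CSV with one header row is also accepted: the first line
    is skipped if it does not parse as a number.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ValueError(f"{path}: empty series file")
    start = 0
    try:
        float(lines[0])
    except ValueError:
        start = 1  # header row
    values = []
    for i, ln in enumerate(lines[start:], start=start + 1):
        try:
            values.append(float(ln))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i} is not a number: {ln!r}") from exc
    return np.asarray(values, dtype=float)


def write_series(x, path) -> None:
    """Write a series as plain text, one decimal value per line (full precision)."""
    x = np.asarray(x, dtype=float)
    Path(path).write_text("".join(f"{v:.17g}\n" for v in x))
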