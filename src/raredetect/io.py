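"""Reading observed-counts tables and writing probability curves.

Counts tables are two-column TSV files (subpopulation name, integer cell
count) with an optional ``subpopulation<TAB>count`` header.  Probability
curves are written as TSV with probabilities at 12 significant digits —
enough to round-trip the computed values to well below any tolerance that
matters for design decisions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CountsTableError
from .posterior import CountsTable

__all__ = ["parse_counts_table", "write_curve_tsv", "read_curve_tsv"]

_HEADER = ("subpopulation", "count")


def parse_counts_table(path: str | Path) -> CountsTable:
    """Read a two-column TSV of per-subpopulation cell counts.

    Raises :class:`CountsTableError` with the offending line number on
    malformed rows (wrong column count, non-integer counts, counts below 1,
    duplicate names).
    """
    names: list[str] = []
    counts: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and tuple(f.strip().lower() for f in fields) == _HEADER:
                continue
            if len(fields) != 2:
                raise CountsTableError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            name, count_str = fields[0].strip(), fields[1].strip()
            try:
                count = int(count_str)
            except ValueError:
                raise CountsTableError(
                    f"{path}: line {lineno}: count {count_str!r} is not an integer"
                ) from None
            if count < 1:
                raise CountsTableError(
                    f"{path}: line {lineno}: count must be >= 1, got {count}"
                )
            if name in names:
                raise CountsTableError(
                    f"{path}: line {lineno}: duplicate subpopulation {name!r}"
                )
            names.append(name)
            counts.append(count)
    if not counts:
        raise CountsTableError(f"{path}: no data rows found")
    return CountsTable(counts=counts, names=names)


def write_curve_tsv(path: str | Path, curve: np.ndarray, columns: list[str]) -> None:
    """Write a probability curve; n as integer, probabilities at 12 sig. digits."""
    arr = np.asarray(curve, dtype=float)
    df = pd.DataFrame(arr, columns=columns)
    df[columns[0]] = df[columns[0]].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for _, row in df.iterrows():
            vals = [str(int(row.iloc[0]))]
            vals += [format(row.iloc[j], ".12g") for j in range(1, len(columns))]
            fh.write("\t".join(vals) + "\n")


def read_curve_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
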