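"""Reading and writing the reads-intersection table and cut-site lists.

The reads-intersection format is a 12-column TSV, one paired-end read per
line::

    chrom1 start1 length1 strand1 up_site1 down_site1
    chrom2 start2 length2 strand2 up_site2 down_site2

``start`` is the 1-based coordinate of the 5' end of the mapped read;
``up_site``/``down_site`` are the closest cut-site coordinates upstream and
downstream of it (informational; classification recomputes them from the
cut-site map).  Strands are ``+``/``-``.  A header line is detected
automatically and gzip compression is transparent (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

INTERSECTION_COLUMNS = [
    "chrom1", "start1", "length1", "strand1", "up_site1", "down_site1",
    "chrom2", "start2", "length2", "strand2", "up_site2", "down_site2",
]

_INT_COLUMNS = [c for c in INTERSECTION_COLUMNS if c not in
                ("chrom1", "chrom2", "strand1", "strand2")]

# unicode minus occasionally survives text round-trips of the strand column
_STRAND = {"+": "+", "-": "-", "−": "-"}


@dataclass
class ParseReport:
    """Per-file accounting of parsed and rejected records."""

    n_lines: int = 0
    n_parsed: int = 0
    n_malformed: int = 0
    errors: list = field(default_factory=list)  # (line number, message), capped
    max_errors: int = 100

    def add_error(self, lineno: int, message: str) -> None:
        self.n_malformed += 1
        if len(self.errors) < self.max_errors:
            self.errors.append((lineno, message))


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


def _parse_line(fields: list[str]) -> tuple:
    if len(fields) != 12:
        raise ValueError(f"expected 12 columns, got {len(fields)}")
    rec = []
    for name, value in zip(INTERSECTION_COLUMNS, fields):
        if name.startswith("chrom"):
            rec.append(value)
        elif name.startswith("strand"):
            try:
                rec.append(_STRAND[value])
            except KeyError:
                raise ValueError(f"bad strand {value!r} in column {name}")
        else:
            try:
                rec.append(int(value))
            except ValueError:
                raise ValueError(f"non-numeric value {value!r} in column {name}")
    return tuple(rec)


def read_intersection_file(path) -> tuple[pd.DataFrame, ParseReport]:
    """Parse a reads-intersection TSV.

    Returns the table of well-formed records and a :class:`ParseReport`
    counting malformed lines (with line numbers).  A missing file raises
    ``FileNotFoundError``; a file whose first line has the wrong column
    count and is not a header raises :class:`FormatError`.
    """
    report = ParseReport()
    records = []
    with _open_text(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if first:
                first = False
                if fields[:1] == ["chrom1"] or fields[0].lstrip("#") == "chrom1":
                    continue  # header
                if len(fields) != 12:
                    raise FormatError(
                        f"{path}: first line has {len(fields)} columns, "
                        "expected 12 (or a header)")
            report.n_lines += 1
            try:
                records.append(_parse_line(fields))
            except ValueError as exc:
                report.add_error(lineno, str(exc))
    if records:
        df = pd.DataFrame.from_records(records, columns=INTERSECTION_COLUMNS)
    else:
        df = empty_reads_table()
    report.n_parsed = len(df)
    return df, report


def empty_reads_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=np.int64) for c in INTERSECTION_COLUMNS})
    for c in ("chrom1", "chrom2", "strand1", "strand2"):
        df[c] = df[c].astype(str)
    return df


def write_intersection_file(reads: pd.DataFrame, path, header: bool = True) -> None:
    """Write a reads table back to the intersection TSV dialect."""
    out = reads[INTERSECTION_COLUMNS]
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False, header=header)


def read_cutsites(path, dialect: str = "bed", chrom: str | None = None,
                  enzyme_name: str = "unknown"):
    """Read a cut-site list.

    ``dialect="bed"``: 3-column BED (chrom, 0-based start, end); the cut-site
    coordinate is ``start + 1`` (1-based).  ``dialect="positions"``: one
    1-based position per line, optionally preceded by a chromosome column.
    """
    from binless.classify import CutSiteMap

    positions = []
    chroms = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if dialect == "bed":
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
                chroms.add(fields[0])
                positions.append(int(fields[1]) + 1)
            elif dialect == "positions":
                if len(fields) >= 2:
                    chroms.add(fields[0])
                    positions.append(int(fields[1]))
                else:
                    positions.append(int(fields[0]))
            else:
                raise ValueError(f"unknown cut-site dialect {dialect!r}")
    if chrom is None:
        if len(chroms) > 1:
            raise FormatError(f"{path}: multiple chromosomes {sorted(chroms)}; "
                              "pass chrom= to select one")
        chrom = chroms.pop() if chroms else "chr"
    positions = np.unique(np.asarray(positions, dtype=np.int64))
    return CutSiteMap(chrom=chrom, positions=positions, enzyme_name=enzyme_name)


def write_cutsites(cutsites, path) -> None:
    """Write cut sites as 3-column BED (0-based start = position - 1)."""
    with _open_text(path, "wt") as fh:
        for p in cutsites.positions:
            fh.write(f"{cutsites.chrom}\t{p - 1}\t{p}\n")
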