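"""The tab-delimited summary-table product: naming, I/O, joins, derivation.

The database is a tree of plain-text, tab-delimited files keyed by HID:

    <root>/ISEA3H<RR>/<Dataset>_V<Version>/
        ISEA3H<RR>_<Dataset>_V<Version>[_Y<Year>[_Y<Year>]]_<Theme>_<Stat>.txt

Column headers are ``<ThemeOrClass>_<Statistic>`` (optionally
``<Theme>_<Class>_<Statistic>`` for integer-coded classes).  Missing
values are written as per-theme null codes; the HID column comes first,
unique and ascending.  Float formatting is fixed per statistic so a
rerun reproduces files byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NamingConvention", "SummaryTable",
    "format_filename", "parse_filename", "column_name",
    "write_table", "read_table", "join_on_hid", "derive_terra",
    "lint_tree",
]

#: decimal places used when serializing each statistic
FLOAT_DIGITS = {"Fraction": 6, "Mean": 4, "Centroid": 4, "IDW": 4}


@dataclass(frozen=True)
class NamingConvention:
    """Components of a summary-table filename."""
    dataset: str
    version: str
    theme: str
    statistic: str
    years: tuple = ()

    def __post_init__(self):
        for part in (self.dataset, self.version, self.theme, self.statistic,
                     *map(str, self.years)):
            if "_" in part or not part:
                raise ValueError(
                    f"filename component {part!r} must be non-empty and "
                    "free of underscores")
        if len(self.years) > 2:
            raise ValueError("at most two Y[Year] components are allowed")


def format_filename(parts: NamingConvention, resolution: int) -> str:
    year_bits = "".join(f"_Y{y}" for y in parts.years)
    return (f"ISEA3H{resolution:02d}_{parts.dataset}_V{parts.version}"
            f"{year_bits}_{parts.theme}_{parts.statistic}.txt")


_NAME_RE = re.compile(
    r"^ISEA3H(?P<res>\d{2})_(?P<dataset>[^_]+)_V(?P<version>[^_]+)"
    r"(?P<years>(?:_Y[^_]+){0,2})_(?P<theme>[^_]+)_(?P<stat>[^_]+)\.txt$")


def parse_filename(name: str):
    """Parse a convention-conformant filename.

    Returns ``(NamingConvention, resolution)``; raises ``ValueError``
    naming the offending component otherwise.
    """
    m = _NAME_RE.match(name)
    if not m:
        for label, pat in [("prefix", r"^ISEA3H\d{2}_"),
                           ("version", r"_V[^_]+"),
                           ("extension", r"\.txt$")]:
            if not re.search(pat, name):
                raise ValueError(f"malformed filename {name!r}: bad {label}")
        raise ValueError(f"malformed filename {name!r}: bad component layout")
    years = tuple(y for y in m.group("years").split("_Y") if y)
    conv = NamingConvention(m.group("dataset"), m.group("version"),
                            m.group("theme"), m.group("stat"), years)
    return conv, int(m.group("res"))


def column_name(theme_or_class: str, statistic: str,
                theme_prefix: str | None = None) -> str:
    """``Af_Fraction``, ``KoppenGeiger_Mode``, ``PREC01_Centroid``, or the
    prefixed form ``IGBP_03_Fraction`` for integer-coded classes."""
    if theme_prefix:
        return f"{theme_prefix}_{theme_or_class}_{statistic}"
    return f"{theme_or_class}_{statistic}"


# ----------------------------------------------------------------------
@dataclass
class SummaryTable:
    """HID-keyed statistic columns plus theme metadata.

    ``data`` is a DataFrame whose index is the unique, ascending HID.
    """
    data: pd.DataFrame
    resolution: int
    naming: NamingConvention | None = None
    null_value: object = None

    def __post_init__(self):
        idx = self.data.index
        if idx.name != "HID":
            raise ValueError("table index must be named HID")
        if idx.has_duplicates:
            raise ValueError("duplicate HIDs in table")
        if not idx.is_monotonic_increasing:
            self.data = self.data.sort_index()


def _fmt(value, digits):
    if digits is None or not isinstance(value, (float, np.floating)):
        return str(value)
    if float(value).is_integer() and abs(value) >= 1:
        # null codes like -100 stay verbatim integers
        return str(int(value))
    return f"{value:.{digits}f}"


def write_table(table: SummaryTable, path) -> None:
    """Write tab-delimited text with a header row (UTF-8, LF endings)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    digits = None
    if table.naming is not None:
        digits = FLOAT_DIGITS.get(table.naming.statistic)
    df = table.data
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["HID", *map(str, df.columns)]) + "\n")
        for hid, row in zip(df.index, df.itertuples(index=False)):
            cells = [str(hid)] + [_fmt(v, digits) for v in row]
            fh.write("\t".join(cells) + "\n")


def read_table(path, resolution: int | None = None) -> SummaryTable:
    """Read a tab-delimited summary table; duplicate HIDs are an error."""
    path = Path(path)
    naming = None
    if resolution is None:
        try:
            naming, resolution = parse_filename(path.name)
        except ValueError:
            resolution = -1
    df = pd.read_csv(path, sep="\t")
    if "HID" not in df.columns:
        raise ValueError("table lacks an HID column")
    if df["HID"].duplicated().any():
        raise ValueError("duplicate HIDs on read: integrity error")
    df = df.set_index("HID")
    return SummaryTable(df, resolution, naming)


def join_on_hid(tables, how: str = "inner") -> SummaryTable:
    """Inner join on HID: the intersection of the tables' cell sets."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to join")
    res = {t.resolution for t in tables}
    if len(res) != 1:
        raise ValueError("tables have differing resolutions")
    out = tables[0].data
    for t in tables[1:]:
        out = out.join(t.data, how=how)
    return SummaryTable(out, tables[0].resolution)


def derive_terra(land: pd.Series, islands: pd.Series,
                 lakes: pd.Series) -> pd.Series:
    """Terrestrial fraction: land + minor islands - lakes, clamped to [0, 1].

    Thresholding the result (e.g. at >= 0.5) identifies terrestrial cells.
    """
    idx = land.index
    if not (idx.equals(islands.index) and idx.equals(lakes.index)):
        raise ValueError("fraction columns must share one HID set")
    return (land + islands - lakes).clip(0.0, 1.0).rename("Terra_Fraction")


# ----------------------------------------------------------------------
def table_path(root, resolution: int, parts: NamingConvention) -> Path:
    """Canonical location of a theme file within the database tree."""
    return (Path(root) / f"ISEA3H{resolution:02d}"
            / f"{parts.dataset}_V{parts.version}"
            / format_filename(parts, resolution))


def lint_tree(root) -> list:
    """Validate a database directory tree against the layout conventions.

    Returns a list of (path, problem) strings; an empty list is a clean
    tree.  Structure is checked (folder naming, file naming, parseability,
    header presence, HID integrity), not numeric content.
    """
    root = Path(root)
    problems = []
    for res_dir in sorted(root.iterdir()):
        if not res_dir.is_dir():
            problems.append((str(res_dir), "stray file at root"))
            continue
        m = re.match(r"^ISEA3H(\d{2})$", res_dir.name)
        if not m:
            problems.append((str(res_dir), "bad resolution folder name"))
            continue
        res = int(m.group(1))
        for ds_dir in sorted(res_dir.iterdir()):
            if not ds_dir.is_dir():
                problems.append((str(ds_dir), "stray file in resolution folder"))
                continue
            if not re.match(r"^[^_]+_V[^_]+$", ds_dir.name):
                problems.append((str(ds_dir), "bad dataset folder name"))
                continue
            for f in sorted(ds_dir.iterdir()):
                try:
                    conv, fres = parse_filename(f.name)
                except ValueError as exc:
                    problems.append((str(f), str(exc)))
                    continue
                if fres != res:
                    problems.append((str(f), "resolution differs from folder"))
                if f"{conv.dataset}_V{conv.version}" != ds_dir.name:
                    problems.append((str(f), "dataset/version differ from folder"))
                try:
                    read_table(f)
                except Exception as exc:
                    problems.append((str(f), f"unreadable: {exc}"))
    return problems
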