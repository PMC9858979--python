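"""Shared helpers: error types, chromosome-label normalization, rounding."""

from __future__ import annotations

import gzip
import io
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

# Allele / phenotype codes used throughout the package.
REF = 0
ALT = 1
MISSING = -2

WT = 0
MUT = 1


class GwaccError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GwaccError):
    """An input file does not conform to its declared format."""


class LocusNotFoundError(GwaccError):
    """A requested (chrom, pos) locus is absent from the genotype table."""


class AmbiguousLocusError(GwaccError):
    """A requested (chrom, pos) locus matches more than one row."""


class ColumnError(GwaccError):
    """A requested column is missing from a delimited input file."""


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label for joining and ordering.

    Strips surrounding whitespace, a leading "chr"/"Chr"/"CHR" prefix and
    leading zeros of numeric labels ("Chr09" -> "9").  The original label is
    kept verbatim elsewhere; normalization is only used for joins, region
    matching and plot ordering.
    """
    s = str(label).strip()
    low = s.lower()
    if low.startswith("chrom"):
        s = s[5:]
    elif low.startswith("chr"):
        s = s[3:]
    if s.isdigit():
        s = s.lstrip("0") or "0"
    return s


def chrom_sort_key(label: str):
    """Natural ordering key: numeric labels first in numeric order, others last."""
    s = normalize_chrom(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (NaN passes through)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_number(x, ndigits: int = 2) -> str:
    """Render a number rounded half-up, trimming trailing zeros; NaN -> "NA".

    Matches the tabular output convention: 98.33 stays "98.33", 81.00
    becomes "81", missing values are written "NA".
    """
    if x is None:
        return "NA"
    try:
        xf = float(x)
    except (TypeError, ValueError):
        return str(x)
    if np.isnan(xf):
        return "NA"
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(xf)).quantize(q, rounding=ROUND_HALF_UP)
    return format(d.normalize(), "f")


def open_text_auto(path) -> io.TextIOBase:
    """Open a possibly gzip-compressed text file, sniffing magic bytes."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")
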