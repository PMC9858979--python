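"""Genotype input/output.

Reads VCF 4.x (plain or gzip/bgzip-compressed, via htslib) and HapMap
``hmp.txt`` (GAPIT dialect) files into a :class:`GenotypeTable`: per-variant
metadata plus a variants x samples matrix of allele codes, where the
reference allele is 0, any alternate allele is 1 and a missing or excluded
call is -2.  Heterozygous diploid calls are resolved by ``het_mode``:
``"missing"`` (default, conservative — the accuracy statistics are defined
for binary REF/ALT classes), ``"alt"`` or ``"ref"``.

Also writes/reads the accuracy result table as delimited text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._util import (
    ALT,
    MISSING,
    REF,
    FormatError,
    format_number,
    normalize_chrom,
    open_text_auto,
)

log = logging.getLogger(__name__)

VARIANT_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]

HET_MODES = ("missing", "alt", "ref")

#: IUPAC two-base ambiguity codes used by single-letter HapMap genotypes.
IUPAC_PAIRS = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}


def _het_code(het_mode: str) -> int:
    if het_mode not in HET_MODES:
        raise ValueError(f"het_mode must be one of {HET_MODES}, got {het_mode!r}")
    return {"missing": MISSING, "alt": ALT, "ref": REF}[het_mode]


@dataclass
class GenotypeTable:
    """Per-variant metadata plus a coded call matrix.

    ``variants`` holds the nine VCF-style metadata columns (one row per
    variant, stably ordered as read); ``calls`` is an int8 matrix of shape
    (n_variants, n_samples) with values in {0, 1, -2}; ``sample_names``
    preserves the input column order.
    """

    variants: pd.DataFrame
    calls: np.ndarray
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        if self.calls.shape != (len(self.variants), len(self.sample_names)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.sample_names)} samples"
            )
        bad = ~np.isin(self.calls, (REF, ALT, MISSING))
        if bad.any():
            raise ValueError(f"calls contain {int(bad.sum())} values outside {{0, 1, -2}}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def chrom_norm(self) -> pd.Series:
        return self.variants["#CHROM"].map(normalize_chrom)

    def locus_rows(self, chrom, pos: int) -> np.ndarray:
        """Row indices whose (chrom, pos) matches after label normalization."""
        want = normalize_chrom(chrom)
        mask = (self.chrom_norm() == want).to_numpy() & (
            self.variants["POS"].to_numpy() == int(pos)
        )
        return np.flatnonzero(mask)

    def subset(self, rows: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            variants=self.variants.iloc[rows].reset_index(drop=True),
            calls=self.calls[rows],
            sample_names=list(self.sample_names),
        )


def _parse_region(region):
    """Accept "chr", "chr:start-end" or a (chrom, start, end) tuple."""
    if region is None:
        return None
    if isinstance(region, str):
        if ":" in region:
            chrom, span = region.split(":", 1)
            start_s, _, end_s = span.partition("-")
            start = int(start_s.replace(",", "")) if start_s else None
            end = int(end_s.replace(",", "")) if end_s else None
            return (chrom, start, end)
        return (region, None, None)
    chrom, start, end = region
    return (chrom, None if start is None else int(start), None if end is None else int(end))


def _check_vcf_header(path) -> None:
    """Require a #CHROM header line before handing the file to htslib."""
    try:
        with open_text_auto(path) as fh:
            for line in fh:
                if line.startswith("#CHROM"):
                    return
                if not line.startswith("#"):
                    break
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    raise FormatError(f"{path}: no #CHROM header line; not a VCF file")


def _code_allele_list(alleles, het_code: int) -> int:
    """Code one sample's called alleles (cyvcf2 integers, -1 = missing)."""
    if len(alleles) == 0:
        return MISSING
    if len(alleles) > 2:
        return MISSING  # ploidy > 2 is outside the biallelic contract
    if any(a < 0 for a in alleles):
        return MISSING
    if all(a == 0 for a in alleles):
        return REF
    if all(a >= 1 for a in alleles):
        return ALT  # any non-reference allele counts as ALT (multiallelic)
    return het_code


def _info_string(record) -> str:
    parts = []
    for key, value in record.INFO:
        if value is True:
            parts.append(key)
        elif isinstance(value, (tuple, list)):
            parts.append(f"{key}={','.join(str(v) for v in value)}")
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts) if parts else "."


def import_vcf(path, region=None, het_mode: str = "missing") -> GenotypeTable:
    """Read a VCF 4.x file (optionally gzip/bgzip-compressed) into a GenotypeTable.

    ``region`` restricts the import to a chromosome or an inclusive
    ``chrom:start-end`` window (linear scan; no index required).  An empty
    region yields an empty table, not an error.
    """
    het = _het_code(het_mode)
    _check_vcf_header(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib signals malformed headers in many ways
        raise FormatError(f"{path}: cannot parse VCF header ({exc})") from exc

    sample_names = list(vcf.samples)
    # gt_types (gts012): 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
    lut = np.array([REF, het, ALT, MISSING], dtype=np.int8)

    reg = _parse_region(region)
    want_chrom = normalize_chrom(reg[0]) if reg else None

    meta_rows = []
    call_rows = []
    n_ploidy_warned = 0
    for rec in vcf:
        if reg is not None:
            if normalize_chrom(rec.CHROM) != want_chrom:
                continue
            if reg[1] is not None and rec.POS < reg[1]:
                continue
            if reg[2] is not None and rec.POS > reg[2]:
                continue
        alt_list = rec.ALT or []
        if len(alt_list) <= 1:
            codes = lut[rec.gt_types]
        else:
            codes = np.empty(len(sample_names), dtype=np.int8)
            for j, g in enumerate(rec.genotypes):
                alleles = g[:-1]  # last element is the phased flag
                if len(alleles) > 2:
                    n_ploidy_warned += 1
                codes[j] = _code_allele_list(alleles, het)
        meta_rows.append(
            (
                rec.CHROM,
                int(rec.POS),
                rec.ID if rec.ID else ".",
                rec.REF,
                ", ".join(alt_list) if alt_list else ".",
                "." if rec.QUAL is None else format_number(rec.QUAL),
                rec.FILTER if rec.FILTER else ".",
                _info_string(rec),
                ":".join(rec.FORMAT) if rec.FORMAT else "GT",
            )
        )
        call_rows.append(codes)
    if n_ploidy_warned:
        warnings.warn(f"{n_ploidy_warned} call(s) with ploidy > 2 coded as missing")

    variants = pd.DataFrame(meta_rows, columns=VARIANT_COLUMNS)
    calls = (
        np.vstack(call_rows)
        if call_rows
        else np.empty((0, len(sample_names)), dtype=np.int8)
    )
    return GenotypeTable(variants=variants, calls=calls, sample_names=sample_names)


def _hapmap_row_map(ref: str, alt: str, het_code: int) -> dict:
    """Token -> code map for one HapMap row (single- and double-letter dialects)."""
    m = {
        "N": MISSING,
        "NN": MISSING,
        ref: REF,
        alt: ALT,
        ref + ref: REF,
        alt + alt: ALT,
        ref + alt: het_code,
        alt + ref: het_code,
    }
    for letter, pair in IUPAC_PAIRS.items():
        if pair == frozenset((ref, alt)):
            m[letter] = het_code
    return m


def import_hapmap(path, het_mode: str = "missing") -> GenotypeTable:
    """Read a HapMap ``hmp.txt`` file (GAPIT dialect) into a GenotypeTable.

    The first 11 columns are metadata (rs#, alleles, chrom, pos, strand,
    assembly, center, protLSID, assayLSID, panel, QCcode), the rest one
    column per sample.  REF is the first allele of the "alleles" field, ALT
    the second; calls are single-letter IUPAC or double-letter genotypes.
    """
    het = _het_code(het_mode)
    with open_text_auto(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 12:
        raise FormatError(
            f"{path}: HapMap needs 11 metadata columns plus at least one sample, "
            f"found {df.shape[1]} columns"
        )
    sample_names = [str(c).strip() for c in df.columns[11:]]
    n_var = len(df)
    calls = np.full((n_var, len(sample_names)), MISSING, dtype=np.int8)
    refs = []
    alts = []
    bad_rows = 0
    raw_calls = df.iloc[:, 11:].to_numpy(dtype=object)
    for i, alleles in enumerate(df.iloc[:, 1].astype(str)):
        parts = alleles.strip().split("/")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            bad_rows += 1
            refs.append(".")
            alts.append(".")
            continue  # whole row stays missing
        ref, alt = parts[0].strip().upper(), parts[1].strip().upper()
        refs.append(ref)
        alts.append(alt)
        row_map = _hapmap_row_map(ref, alt, het)
        for j in range(len(sample_names)):
            calls[i, j] = row_map.get(str(raw_calls[i, j]).strip().upper(), MISSING)
    if bad_rows:
        warnings.warn(f"{bad_rows} HapMap row(s) with malformed alleles field coded missing")

    variants = pd.DataFrame(
        {
            "#CHROM": df.iloc[:, 2].astype(str),
            "POS": df.iloc[:, 3].astype(int),
            "ID": df.iloc[:, 0].astype(str),
            "REF": refs,
            "ALT": alts,
            "QUAL": ".",
            "FILTER": ".",
            "INFO": ".",
            "FORMAT": "GT",
        }
    )
    return GenotypeTable(variants=variants, calls=calls, sample_names=sample_names)


def extract_effect(info: str) -> str:
    """Extract the functional-effect label from a SnpEff-style INFO string.

    Returns the annotation term of the first ``ANN=``/``EFF=`` entry, with
    the protein change (HGVS.p) appended when present, e.g.
    ``"missense_variant p.Ala25Thr"``; ``"."`` when absent or malformed.
    """
    if not info or info == ".":
        return "."
    ann = None
    for part in str(info).split(";"):
        if part.startswith("ANN=") or part.startswith("EFF="):
            ann = part.split("=", 1)[1]
            break
    if not ann:
        return "."
    first = ann.split(",")[0]
    fields = first.split("|")
    if len(fields) < 2 or not fields[1]:
        return "."
    term = fields[1]
    aa = next((f for f in fields[2:] if f.startswith("p.")), "")
    return f"{term} {aa}" if aa else term


#: Columns of the accuracy table rendered as rounded percentages / numbers.
NUMERIC_EXPORT_COLUMNS = [
    "Acc_WT",
    "Acc_MUT",
    "Avr_acc",
    "Comb_acc_real",
    "Acc_pes_WT",
    "Acc_pes_MUT",
    "Avr_acc_pes",
    "Comb_acc_pes",
    "Missing_WT_gen",
    "Missing_MUT_gen",
    "neg_log10_p",
]

METADATA_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "INFO"]


def write_accuracy_table(table, path, sep: str = ",") -> None:
    """Write an accuracy table as delimited text.

    The six locus-metadata columns come first, then every statistic column;
    percentages are rounded half-up to 2 decimals and missing values are
    written as "NA".
    """
    df = table.data.copy()
    ordered = METADATA_COLUMNS + [c for c in df.columns if c not in METADATA_COLUMNS]
    df = df[ordered]
    for col in df.columns:
        if col in NUMERIC_EXPORT_COLUMNS:
            df[col] = df[col].map(format_number)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")
    log.info("wrote accuracy table with %d rows to %s", len(df), path)


def read_accuracy_table(path, sep: str = ","):
    """Read back a table written by :func:`write_accuracy_table`."""
    from .accuracy import AccuracyTable

    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False)
    if "Flipped" in df.columns:
        df["Flipped"] = df["Flipped"].map(lambda v: str(v).strip().lower() == "true")
    return AccuracyTable(data=df)
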