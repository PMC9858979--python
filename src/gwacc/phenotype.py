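"""Binary phenotype import, alignment, synthetic construction and export.

Phenotypes are coded 0 (wild type, WT), 1 (mutant, MUT) and -2 (missing /
excluded, serialized as "NA").  A synthetic phenotype re-uses the allele
calls of a chosen tagging-marker locus as a stand-in phenotype, which lets
a resequenced panel without recorded phenotypes be scanned for candidate
causative mutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import (
    MISSING,
    MUT,
    WT,
    FormatError,
    GwaccError,
    AmbiguousLocusError,
    LocusNotFoundError,
    normalize_chrom,
)

log = logging.getLogger(__name__)


@dataclass
class PhenotypeTable:
    """Ordered sample -> phenotype-code map (codes in {0, 1, -2})."""

    sample_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_names = [str(s) for s in self.sample_names]
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_names):
            raise ValueError("values must be a vector matching sample_names")
        bad = ~np.isin(self.values, (WT, MUT, MISSING))
        if bad.any():
            raise ValueError(f"{int(bad.sum())} phenotype value(s) outside {{0, 1, -2}}")
        seen = set()
        dups = [s for s in self.sample_names if s in seen or seen.add(s)]
        if dups:
            raise GwaccError(f"duplicate sample names: {sorted(set(dups))}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def tallies(self) -> tuple[int, int, int]:
        """(n_WT, n_MUT, n_missing) class sizes."""
        v = self.values
        return int((v == WT).sum()), int((v == MUT).sum()), int((v == MISSING).sum())


def import_phenotype(path, wt_label: str = "0", mut_label: str = "1") -> PhenotypeTable:
    """Read a two-column tab-delimited phenotype file (header + sample/value rows).

    Values equal to ``wt_label`` map to 0, ``mut_label`` to 1, anything else
    (NA, blank, other labels) to -2.  Arbitrary trait labels ("purple",
    "white", ...) are supported through the two label arguments.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: phenotype file needs 2 tab-delimited columns")
    names = df.iloc[:, 0].astype(str).str.strip().tolist()
    raw = df.iloc[:, 1].astype(str).str.strip()
    values = np.full(len(raw), MISSING, dtype=np.int8)
    values[(raw == str(wt_label)).to_numpy()] = WT
    values[(raw == str(mut_label)).to_numpy()] = MUT
    table = PhenotypeTable(sample_names=names, values=values)
    n_wt, n_mut, n_na = table.tallies()
    log.info(
        "phenotype %s: %r->WT (%d), %r->MUT (%d), other->NA (%d)",
        path, wt_label, n_wt, mut_label, n_mut, n_na,
    )
    return table


def align_samples(phen: PhenotypeTable, gen) -> PhenotypeTable:
    """Reorder a phenotype to the genotype's sample order.

    Samples present in the genotype but absent from the phenotype get NA
    (-2); phenotype samples absent from the genotype are dropped with a
    warning.  The result always has exactly the genotype's samples, in
    order, so ``align(align(p, g), g) == align(p, g)``.
    """
    lookup = dict(zip(phen.sample_names, phen.values))
    gen_names = [str(s) for s in gen.sample_names]
    values = np.array([lookup.get(s, MISSING) for s in gen_names], dtype=np.int8)
    dropped = [s for s in phen.sample_names if s not in set(gen_names)]
    if dropped:
        warnings.warn(
            f"{len(dropped)} phenotype sample(s) absent from genotype, dropped: "
            f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}"
        )
    return PhenotypeTable(sample_names=gen_names, values=values)


def _invert(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    out[values == WT] = MUT
    out[values == MUT] = WT
    return out


def synthetic_from_table(gen, chrom, pos: int, ref_is: str = "wt") -> PhenotypeTable:
    """Build a synthetic phenotype from one locus of a genotype table.

    With ``ref_is="wt"`` (default) carriers of the reference allele become
    WT (0) and carriers of the alternate allele MUT (1); ``ref_is="mut"``
    inverts the mapping.  Missing calls stay missing.
    """
    if ref_is not in ("wt", "mut"):
        raise ValueError(f"ref_is must be 'wt' or 'mut', got {ref_is!r}")
    rows = gen.locus_rows(chrom, pos)
    if len(rows) == 0:
        chrom_mask = (gen.chrom_norm() == normalize_chrom(chrom)).to_numpy()
        positions = gen.variants["POS"].to_numpy()[chrom_mask]
        if len(positions):
            nearest = positions[np.argsort(np.abs(positions - int(pos)))[:3]]
            hint = f"; nearest positions on that chromosome: {sorted(int(p) for p in nearest)}"
        else:
            hint = "; chromosome not present"
        raise LocusNotFoundError(f"locus {chrom}:{pos} not found{hint}")
    if len(rows) > 1:
        raise AmbiguousLocusError(
            f"locus {chrom}:{pos} matches {len(rows)} rows (indices {rows.tolist()}); "
            "disambiguate by subsetting the genotype table to one row index"
        )
    values = gen.calls[rows[0]].astype(np.int8)  # 0->WT, 1->MUT, -2->NA
    if ref_is == "mut":
        values = _invert(values)
    return PhenotypeTable(sample_names=list(gen.sample_names), values=values)


def synthetic_from_vcf(path, chrom, pos: int, ref_is: str = "wt",
                       het_mode: str = "missing") -> PhenotypeTable:
    """Build a synthetic phenotype directly from one locus of a VCF file."""
    from .genotype_io import import_vcf

    gen = import_vcf(path, region=(chrom, int(pos), int(pos)), het_mode=het_mode)
    return synthetic_from_table(gen, chrom, pos, ref_is=ref_is)


def export_phenotype(phen: PhenotypeTable, name) -> str:
    """Write a phenotype as a two-column tab-delimited text file.

    The ".txt" suffix is appended automatically when absent; -2 is written
    as "NA".  Returns the path written.
    """
    path = str(name)
    if not path.endswith(".txt"):
        path += ".txt"
    codes = ["NA" if v == MISSING else str(int(v)) for v in phen.values]
    pd.DataFrame({"sample": phen.sample_names, "phenotype": codes}).to_csv(
        path, sep="\t", index=False
    )
    return path
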