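"""Per-variant genotype-phenotype concordance ("accuracy") statistics.

For every variant the samples of known phenotype are cross-tabulated into
the four classes WT-REF, WT-ALT, MUT-REF, MUT-ALT (samples with a missing
genotype contribute only to the class totals N_WT, N_MUT, N_ALL).  Eight
statistics on a 0-100 % scale follow:

realistic (samples with known genotype only)
    Acc_WT        = 100 * N_WT-REF / (N_WT-REF + N_WT-ALT)
    Acc_MUT       = 100 * N_MUT-ALT / (N_MUT-REF + N_MUT-ALT)
    Avr_acc       = (Acc_WT + Acc_MUT) / 2
    Comb_acc_real = 100 * (N_WT-REF + N_MUT-ALT)
                        / (N_WT-REF + N_WT-ALT + N_MUT-REF + N_MUT-ALT)

pessimistic (missing genotypes count against the accuracy)
    Acc_pes_WT    = 100 * N_WT-REF / N_WT
    Acc_pes_MUT   = 100 * N_MUT-ALT / N_MUT
    Avr_acc_pes   = (Acc_pes_WT + Acc_pes_MUT) / 2
    Comb_acc_pes  = 100 * (N_WT-REF + N_MUT-ALT) / N_ALL,  N_ALL = N_WT + N_MUT

A zero denominator makes the statistic undefined (NaN), and an undefined
component makes its average undefined.  The pessimistic variants penalize
missing data, which matters most for strongly disproportional phenotypes
(one mutant among hundreds of wild types): there a single missing mutant
genotype erases all evidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from math import nan

import numpy as np
import pandas as pd

from ._util import (
    ALT,
    MISSING,
    MUT,
    REF,
    WT,
    ColumnError,
    GwaccError,
    normalize_chrom,
)
from .genotype_io import extract_effect

log = logging.getLogger(__name__)

#: Accuracy-statistic columns of an AccuracyTable, in output order.
STAT_COLUMNS = [
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
]


@dataclass(frozen=True)
class ClassCounts:
    """Per-variant contingency counts over samples of known phenotype."""

    n_wt_ref: int
    n_wt_alt: int
    n_mut_ref: int
    n_mut_alt: int
    n_wt: int
    n_mut: int

    @property
    def n_all(self) -> int:
        return self.n_wt + self.n_mut

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.n_wt_ref + self.n_wt_alt > self.n_wt:
            raise ValueError("n_wt_ref + n_wt_alt exceeds n_wt")
        if self.n_mut_ref + self.n_mut_alt > self.n_mut:
            raise ValueError("n_mut_ref + n_mut_alt exceeds n_mut")

    def swapped(self) -> "ClassCounts":
        """Counts with the REF/ALT allele roles exchanged."""
        return ClassCounts(
            n_wt_ref=self.n_wt_alt,
            n_wt_alt=self.n_wt_ref,
            n_mut_ref=self.n_mut_alt,
            n_mut_alt=self.n_mut_ref,
            n_wt=self.n_wt,
            n_mut=self.n_mut,
        )


@dataclass(frozen=True)
class AccuracyRecord:
    """All accuracy statistics for one variant (percent scale; NaN = undefined)."""

    acc_wt: float
    acc_mut: float
    avr_acc: float
    comb_acc_real: float
    acc_pes_wt: float
    acc_pes_mut: float
    avr_acc_pes: float
    comb_acc_pes: float
    missing_wt_gen: float
    missing_mut_gen: float
    flipped: bool = False
    neglog10p: float = nan


@dataclass
class AccuracyTable:
    """Variant metadata plus one accuracy record per variant (a DataFrame)."""

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    def metric_values(self, metric: str) -> np.ndarray:
        if metric not in self.data.columns:
            raise ColumnError(
                f"unknown metric {metric!r}; available: {list(self.data.columns)}"
            )
        return self.data[metric].to_numpy(dtype=float)


def count_classes(calls, phen_values) -> ClassCounts:
    """Tally one variant's contingency counts from aligned code vectors.

    Samples with phenotype -2 are excluded entirely; samples with genotype
    -2 count only toward N_WT / N_MUT / N_ALL.
    """
    calls = np.asarray(calls)
    phen_values = np.asarray(phen_values)
    if calls.shape != phen_values.shape:
        raise GwaccError(
            f"length mismatch: {calls.shape} calls vs {phen_values.shape} phenotypes"
        )
    wt = phen_values == WT
    mut = phen_values == MUT
    return ClassCounts(
        n_wt_ref=int((wt & (calls == REF)).sum()),
        n_wt_alt=int((wt & (calls == ALT)).sum()),
        n_mut_ref=int((mut & (calls == REF)).sum()),
        n_mut_alt=int((mut & (calls == ALT)).sum()),
        n_wt=int(wt.sum()),
        n_mut=int(mut.sum()),
    )


def _stats_arrays(nwr, nwa, nmr, nma, n_wt, n_mut):
    """Vectorized statistics from count arrays; zero denominators give NaN."""
    nwr = np.asarray(nwr, dtype=float)
    nwa = np.asarray(nwa, dtype=float)
    nmr = np.asarray(nmr, dtype=float)
    nma = np.asarray(nma, dtype=float)
    n_wt = np.broadcast_to(np.asarray(n_wt, dtype=float), nwr.shape)
    n_mut = np.broadcast_to(np.asarray(n_mut, dtype=float), nwr.shape)

    def ratio(num, den):
        return np.where(den > 0, 100.0 * num / np.where(den > 0, den, 1.0), np.nan)

    acc_wt = ratio(nwr, nwr + nwa)
    acc_mut = ratio(nma, nmr + nma)
    avr_acc = (acc_wt + acc_mut) / 2.0
    comb_real = ratio(nwr + nma, nwr + nwa + nmr + nma)
    acc_pes_wt = ratio(nwr, n_wt)
    acc_pes_mut = ratio(nma, n_mut)
    avr_pes = (acc_pes_wt + acc_pes_mut) / 2.0
    comb_pes = ratio(nwr + nma, n_wt + n_mut)
    missing_wt = ratio(n_wt - nwr - nwa, n_wt)
    missing_mut = ratio(n_mut - nmr - nma, n_mut)
    return {
        "Acc_WT": acc_wt,
        "Acc_MUT": acc_mut,
        "Avr_acc": avr_acc,
        "Comb_acc_real": comb_real,
        "Acc_pes_WT": acc_pes_wt,
        "Acc_pes_MUT": acc_pes_mut,
        "Avr_acc_pes": avr_pes,
        "Comb_acc_pes": comb_pes,
        "Missing_WT_gen": missing_wt,
        "Missing_MUT_gen": missing_mut,
    }


def accuracy_from_counts(c: ClassCounts, flipped: bool = False) -> AccuracyRecord:
    """All eight accuracy statistics (plus missingness) from one set of counts."""
    s = _stats_arrays(
        np.array([c.n_wt_ref]),
        np.array([c.n_wt_alt]),
        np.array([c.n_mut_ref]),
        np.array([c.n_mut_alt]),
        c.n_wt,
        c.n_mut,
    )
    return AccuracyRecord(
        acc_wt=float(s["Acc_WT"][0]),
        acc_mut=float(s["Acc_MUT"][0]),
        avr_acc=float(s["Avr_acc"][0]),
        comb_acc_real=float(s["Comb_acc_real"][0]),
        acc_pes_wt=float(s["Acc_pes_WT"][0]),
        acc_pes_mut=float(s["Acc_pes_MUT"][0]),
        avr_acc_pes=float(s["Avr_acc_pes"][0]),
        comb_acc_pes=float(s["Comb_acc_pes"][0]),
        missing_wt_gen=float(s["Missing_WT_gen"][0]),
        missing_mut_gen=float(s["Missing_MUT_gen"][0]),
        flipped=flipped,
    )


def calc_accuracy(gen, phen, cal: str = "ref_is_wt", flip: bool = False) -> AccuracyTable:
    """Compute the accuracy table for every variant of a genotype table.

    ``cal`` sets which phenotype class the reference genome is assumed to
    carry: ``"ref_is_wt"`` (default) scores REF alleles as wild type,
    ``"ref_is_mut"`` swaps the allele roles before counting.  With
    ``flip=True`` both orientations are evaluated per variant and the one
    with the larger Avr_acc is reported (ties, or both undefined, keep the
    ``cal`` orientation; a defined Avr_acc beats an undefined one), with the
    ``Flipped`` column recording the choice.
    """
    if cal not in ("ref_is_wt", "ref_is_mut"):
        raise ValueError(f"cal must be 'ref_is_wt' or 'ref_is_mut', got {cal!r}")
    from .phenotype import align_samples

    if list(phen.sample_names) != [str(s) for s in gen.sample_names]:
        phen = align_samples(phen, gen)
    pv = phen.values
    known = pv != MISSING
    overlap = int(known.sum())
    if overlap == 0:
        raise GwaccError("no overlapping samples with known phenotype between inputs")
    n_wt = int((pv == WT).sum())
    n_mut = int((pv == MUT).sum())
    log.info("scoring %d variants: %d WT, %d MUT, %d NA samples",
             gen.n_variants, n_wt, n_mut, int((pv == MISSING).sum()))

    calls = gen.calls
    wt = pv == WT
    mut = pv == MUT
    nwr = (calls[:, wt] == REF).sum(axis=1)
    nwa = (calls[:, wt] == ALT).sum(axis=1)
    nmr = (calls[:, mut] == REF).sum(axis=1)
    nma = (calls[:, mut] == ALT).sum(axis=1)
    if cal == "ref_is_mut":
        nwr, nwa, nmr, nma = nwa, nwr, nma, nmr

    primary = _stats_arrays(nwr, nwa, nmr, nma, n_wt, n_mut)
    if flip:
        swapped = _stats_arrays(nwa, nwr, nma, nmr, n_wt, n_mut)
        a, b = primary["Avr_acc"], swapped["Avr_acc"]
        with np.errstate(invalid="ignore"):
            flipped = (b > a) | (np.isnan(a) & ~np.isnan(b))
        stats = {k: np.where(flipped, swapped[k], primary[k]) for k in primary}
        if flipped.any():
            log.info("flip: %d of %d variants reported in swapped orientation",
                     int(flipped.sum()), gen.n_variants)
    else:
        flipped = np.zeros(gen.n_variants, dtype=bool)
        stats = primary

    meta = gen.variants
    data = pd.DataFrame(
        {
            "#CHROM": meta["#CHROM"].to_numpy(),
            "POS": meta["POS"].to_numpy(),
            "ID": meta["ID"].to_numpy(),
            "REF": meta["REF"].to_numpy(),
            "ALT": meta["ALT"].to_numpy(),
            "INFO": meta["INFO"].to_numpy(),
            "Effect": meta["INFO"].map(extract_effect).to_numpy(),
            **{k: stats[k] for k in STAT_COLUMNS},
            "Count_WT": n_wt,
            "Count_MUT": n_mut,
            "Flipped": flipped,
        }
    )
    return AccuracyTable(data=data)


#: Column presets for common GWAS result dialects.
PVAL_PRESETS = {
    "gapit": {"chrom": "Chromosome", "pos": "Position", "p": "P.value"},
    "plink": {"chrom": "CHR", "pos": "BP", "p": "P"},
    "tassel": {"chrom": "Chr", "pos": "Pos", "p": "p"},
}


def add_pvalues(acc: AccuracyTable, results_path, colmap: dict | None = None,
                preset: str | None = None, p_is_neglog: bool = False,
                sep: str | None = None) -> AccuracyTable:
    """Join -log10(p) values from a GWAS results file onto an accuracy table.

    ``colmap`` maps the keys "chrom"/"pos"/"p" to column names (or 0-based
    integer positions) of the results file; ``preset`` selects a known
    dialect instead ("gapit", "plink", "tassel").  The join key is the
    normalized (chrom, pos) pair; unmatched variants get NA.  Duplicate
    positions in the results keep the smallest p with a warning.
    """
    if colmap is None:
        if preset is None:
            preset = "gapit"
        try:
            colmap = PVAL_PRESETS[preset]
        except KeyError:
            raise ColumnError(
                f"unknown preset {preset!r}; available: {sorted(PVAL_PRESETS)}"
            ) from None
    missing_keys = {"chrom", "pos", "p"} - set(colmap)
    if missing_keys:
        raise ColumnError(f"colmap lacks required keys: {sorted(missing_keys)}")

    res = pd.read_csv(results_path, sep=sep, engine="python" if sep is None else "c")

    def pick(key):
        sel = colmap[key]
        if isinstance(sel, int):
            if sel >= res.shape[1]:
                raise ColumnError(
                    f"column index {sel} out of range; file has {res.shape[1]} columns"
                )
            return res.iloc[:, sel]
        if sel not in res.columns:
            raise ColumnError(
                f"column {sel!r} not in results file; available: {list(res.columns)}"
            )
        return res[sel]

    key = pd.DataFrame(
        {
            "chrom": pick("chrom").map(normalize_chrom),
            "pos": pick("pos").astype(float).astype(int),
            "p": pick("p").astype(float),
        }
    )
    if p_is_neglog:
        key["neglog"] = key["p"]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            neglog = -np.log10(key["p"].to_numpy())
        bad = ~np.isfinite(neglog)
        if bad.any():
            warnings.warn(f"{int(bad.sum())} p-value(s) outside (0, 1] set to NA")
            neglog[bad] = np.nan
        key["neglog"] = neglog

    n_dup = int(key.duplicated(subset=["chrom", "pos"]).sum())
    if n_dup:
        warnings.warn(f"{n_dup} duplicate (chrom, pos) row(s) in results; smallest p kept")
    best = (
        key.sort_values("neglog", ascending=False)
        .drop_duplicates(subset=["chrom", "pos"], keep="first")
        .set_index(["chrom", "pos"])["neglog"]
    )

    data = acc.data.copy()
    idx = pd.MultiIndex.from_arrays(
        [data["#CHROM"].map(normalize_chrom), data["POS"].astype(int)]
    )
    data["neg_log10_p"] = best.reindex(idx).to_numpy()
    n_matched = int(np.isfinite(data["neg_log10_p"]).sum())
    log.info("p-value join: %d of %d variants matched", n_matched, len(data))
    return AccuracyTable(data=data)


def filter_accuracy(acc: AccuracyTable, metric: str = "Avr_acc",
                    threshold: float = 80.0, keep: str = "gt") -> AccuracyTable:
    """Keep rows whose ``metric`` passes the threshold (NA rows drop out).

    ``keep="ge"`` retains metric >= threshold, ``keep="gt"`` strictly
    greater.  Row order is preserved.
    """
    if keep not in ("ge", "gt"):
        raise ValueError(f"keep must be 'ge' or 'gt', got {keep!r}")
    values = acc.metric_values(metric)
    with np.errstate(invalid="ignore"):
        mask = values >= threshold if keep == "ge" else values > threshold
    mask &= np.isfinite(values)
    return AccuracyTable(data=acc.data.loc[mask].copy())
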