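"""Synthetic cohort generation with known ground-truth contingency counts.

The simulator emits matched VCF / HapMap / phenotype / GWAS-results files
describing one cohort, together with the exact per-variant class counts
tallied *during* generation — so the accuracy pipeline can be validated
against an oracle that never ran through the code under test.  It models
only the contingency structure the accuracy statistics consume (class
sizes, per-variant concordance, missingness); it makes no attempt at
population-genetic realism (no LD, no allele-frequency spectrum, only
homozygous calls).

Defaults mirror the proportional soybean flower-color study design:
42 wild-type (purple) and 98 mutant (white) accessions plus a handful of
unphenotyped samples.  :func:`glabrous_case_tables` builds the opposite
extreme — the deterministic 299-pubescent / 1-glabrous benchmark over the
12 fully concordant variants around the ss715604810 tagging marker on
soybean chromosome 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ALT, MISSING, MUT, REF, WT
from .accuracy import ClassCounts
from .genotype_io import GenotypeTable, VARIANT_COLUMNS
from .phenotype import PhenotypeTable, export_phenotype

BASES = np.array(list("ACGT"))

ALL_FORMATS = ("vcf", "hapmap", "phenotype", "gwas_results")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cohort.

    concordance is the probability that a WT sample carries REF and a MUT
    sample carries ALT at a variant; 1.0 yields perfect correspondence
    (Avr_acc 100), 0.5 no correspondence beyond chance (Avr_acc near 50).
    """

    n_wt: int = 42
    n_mut: int = 98
    n_variants: int = 100
    concordance: float = 0.9
    missing_gen_rate: float = 0.02
    missing_phen_rate: float = 0.05
    seed: int = 0
    n_chrom: int = 2
    formats: tuple = ALL_FORMATS

    def __post_init__(self) -> None:
        for name in ("concordance", "missing_gen_rate", "missing_phen_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_wt", "n_mut", "n_variants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.formats) - set(ALL_FORMATS)
        if unknown:
            raise ValueError(f"unknown formats: {sorted(unknown)}")


def _simulate_tables(spec: SimulationSpec):
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_wt + spec.n_mut
    sample_names = [f"S{i + 1:04d}" for i in range(n_samples)]

    phen = np.concatenate(
        [np.full(spec.n_wt, WT, dtype=np.int8), np.full(spec.n_mut, MUT, dtype=np.int8)]
    )
    rng.shuffle(phen)
    phen[rng.random(n_samples) < spec.missing_phen_rate] = MISSING

    # Concordant draw: WT->REF, MUT->ALT with prob `concordance`; unknown
    # phenotypes carry either allele at random.
    u = rng.random((spec.n_variants, n_samples))
    concordant = u < spec.concordance
    calls = np.empty((spec.n_variants, n_samples), dtype=np.int8)
    calls[:, phen == WT] = np.where(concordant[:, phen == WT], REF, ALT)
    calls[:, phen == MUT] = np.where(concordant[:, phen == MUT], ALT, REF)
    na = phen == MISSING
    calls[:, na] = np.where(rng.random((spec.n_variants, int(na.sum()))) < 0.5, REF, ALT)
    calls[rng.random(calls.shape) < spec.missing_gen_rate] = MISSING

    chroms = np.sort(rng.integers(1, spec.n_chrom + 1, size=spec.n_variants))
    pos = np.empty(spec.n_variants, dtype=np.int64)
    for c in np.unique(chroms):
        k = int((chroms == c).sum())
        pos[chroms == c] = np.sort(
            rng.choice(np.arange(1, 50_000_000), size=k, replace=False)
        )
    ref_idx = rng.integers(0, 4, size=spec.n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=spec.n_variants)) % 4

    variants = pd.DataFrame(
        {
            "#CHROM": chroms.astype(str),
            "POS": pos,
            "ID": [f"sv{i + 1:05d}" for i in range(spec.n_variants)],
            "REF": BASES[ref_idx],
            "ALT": BASES[alt_idx],
            "QUAL": ".",
            "FILTER": ".",
            "INFO": ".",
            "FORMAT": "GT",
        }
    )
    gen = GenotypeTable(variants=variants, calls=calls, sample_names=sample_names)
    phen_table = PhenotypeTable(sample_names=sample_names, values=phen)
    pvalues = rng.uniform(1e-8, 1.0, size=spec.n_variants)
    return gen, phen_table, pvalues


def _tally_truth(gen: GenotypeTable, phen: PhenotypeTable) -> pd.DataFrame:
    """Per-variant ClassCounts realized in the generated matrices."""
    pv = phen.values
    wt = pv == WT
    mut = pv == MUT
    c = gen.calls
    return pd.DataFrame(
        {
            "#CHROM": gen.variants["#CHROM"],
            "POS": gen.variants["POS"],
            "n_wt_ref": (c[:, wt] == REF).sum(axis=1),
            "n_wt_alt": (c[:, wt] == ALT).sum(axis=1),
            "n_mut_ref": (c[:, mut] == REF).sum(axis=1),
            "n_mut_alt": (c[:, mut] == ALT).sum(axis=1),
            "n_wt": int(wt.sum()),
            "n_mut": int(mut.sum()),
        }
    )


GT_TOKEN = {REF: "0/0", ALT: "1/1", MISSING: "./."}


def write_vcf(gen: GenotypeTable, path) -> str:
    """Write a GenotypeTable as a plain-text VCF 4.2 file (homozygous codes)."""
    path = str(path)
    tokens = np.array([GT_TOKEN[REF], GT_TOKEN[ALT], GT_TOKEN[MISSING]])
    idx = np.select(
        [gen.calls == REF, gen.calls == ALT], [0, 1], default=2
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen = []
        for c in gen.variants["#CHROM"].astype(str):
            if c not in seen:
                seen.append(c)
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#" + "\t".join(c.lstrip("#") for c in VARIANT_COLUMNS))
        fh.write("\t" + "\t".join(gen.sample_names) + "\n")
        meta = gen.variants.astype(str).to_numpy()
        for i in range(gen.n_variants):
            row = meta[i].tolist()
            row[4] = row[4].replace(", ", ",")  # VCF wants bare comma lists
            fh.write("\t".join(row) + "\t" + "\t".join(tokens[idx[i]].tolist()) + "\n")
    return path


def write_hapmap(gen: GenotypeTable, path) -> str:
    """Write a GenotypeTable as a single-letter HapMap hmp.txt file (SNPs only)."""
    path = str(path)
    header = [
        "rs#", "alleles", "chrom", "pos", "strand", "assembly", "center",
        "protLSID", "assayLSID", "panel", "QCcode",
    ] + list(gen.sample_names)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(gen.n_variants):
            v = gen.variants.iloc[i]
            ref, alt = str(v["REF"]), str(v["ALT"]).split(",")[0].strip()
            letters = {REF: ref, ALT: alt, MISSING: "N"}
            meta = [
                str(v["ID"]), f"{ref}/{alt}", str(v["#CHROM"]), str(v["POS"]),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fh.write("\t".join(meta + [letters[int(c)] for c in gen.calls[i]]) + "\n")
    return path


def write_gwas_results(gen: GenotypeTable, pvalues, path) -> str:
    """Write a GAPIT-dialect GWAS results CSV (Chromosome, Position, P.value)."""
    path = str(path)
    pd.DataFrame(
        {
            "Chromosome": gen.variants["#CHROM"],
            "Position": gen.variants["POS"],
            "P.value": pvalues,
        }
    ).to_csv(path, index=False)
    return path


def generate(spec: SimulationSpec, outdir) -> dict:
    """Generate one cohort and write the requested formats.

    Returns a dict with the in-memory tables, the written file paths, the
    drawn p-values and ``truth`` — the per-variant ClassCounts realized in
    the generated matrix, tallied during generation.  Identical specs
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen, phen, pvalues = _simulate_tables(spec)
    out = {
        "genotype": gen,
        "phenotype": phen,
        "pvalues": pvalues,
        "truth": _tally_truth(gen, phen),
        "paths": {},
    }
    if "vcf" in spec.formats:
        out["paths"]["vcf"] = write_vcf(gen, outdir / "cohort.vcf")
    if "hapmap" in spec.formats:
        out["paths"]["hapmap"] = write_hapmap(gen, outdir / "cohort.hmp.txt")
    if "phenotype" in spec.formats:
        out["paths"]["phenotype"] = export_phenotype(phen, str(outdir / "phenotype"))
    if "gwas_results" in spec.formats:
        out["paths"]["gwas_results"] = write_gwas_results(
            gen, pvalues, outdir / "gwas_results.csv"
        )
    return out


def truth_counts(row) -> ClassCounts:
    """ClassCounts from one row of the generator's truth table."""
    return ClassCounts(
        n_wt_ref=int(row["n_wt_ref"]),
        n_wt_alt=int(row["n_wt_alt"]),
        n_mut_ref=int(row["n_mut_ref"]),
        n_mut_alt=int(row["n_mut_alt"]),
        n_wt=int(row["n_wt"]),
        n_mut=int(row["n_mut"]),
    )


# ---------------------------------------------------------------------------
# Deterministic glabrous-pubescence benchmark (rare-phenotype extreme).
#
# 300 soybean accessions — 299 pubescent wild types and a single glabrous
# mutant — over the 12 variant positions in the 4 Mbp window around the
# ss715604810 tagging marker (chromosome 9) that correspond perfectly to
# the phenotype: every scored WT carries REF, the mutant carries ALT, and
# only the number of missing WT genotypes differs between variants.  The
# missense variant in Glyma.09g278000 (p.Ala25Thr) is the causative one.
# ---------------------------------------------------------------------------

#: (pos, ref, alt, gene, effect term, HGVS.p, -log10 p, n missing WT genotypes)
GLABROUS_VARIANTS = [
    (46_340_547, "A", "G, C", "Glyma.09g241100", "intron_variant", "", 0.26, 4),
    (47_953_315, "G", "A", "Glyma.09g261600", "upstream_gene_variant", "", 0.26, 4),
    (47_318_232, "G", "A", "Glyma.09g253300", "upstream_gene_variant", "", 0.26, 5),
    (47_124_449, "C", "G", "Glyma.09g250500", "intron_variant", "", 0.26, 5),
    (48_649_742, "G", "C", "Glyma.09g269100", "downstream_gene_variant", "", 0.26, 5),
    (49_336_581, "G", "A", "Glyma.09g278000", "missense_variant", "p.Ala25Thr", 0.26, 5),
    (48_879_536, "C", "T", "Glyma.09g272300", "intron_variant", "", 0.26, 5),
    (45_868_448, "G", "A", "", "intergenic_region", "", 0.27, 7),
    (46_493_848, "A", "G", "", "intergenic_region", "", 0.22, 11),
    (46_863_256, "A", "G", "Glyma.09g247100", "upstream_gene_variant", "", 0.01, 50),
    (46_897_306, "A", "C", "Glyma.09g247500", "intron_variant", "", 0.23, 57),
    (47_196_829, "T", "TATGA, TATGTATATGA", "Glyma.09g251500", "intron_variant", "", 0.43, 63),
]

GLABROUS_N_WT = 299
GLABROUS_N_MUT = 1


def glabrous_case_tables() -> tuple[GenotypeTable, PhenotypeTable]:
    """The deterministic 299-WT / 1-MUT benchmark (12 variants x 300 samples).

    Per variant, the first k WT samples (k from the variant's missing-WT
    count) have a missing genotype, every other WT carries REF, and the
    single mutant carries ALT.
    """
    sample_names = [f"acc{i + 1:04d}" for i in range(GLABROUS_N_WT)] + ["glabrous01"]
    phen = PhenotypeTable(
        sample_names=sample_names,
        values=np.array([WT] * GLABROUS_N_WT + [MUT], dtype=np.int8),
    )
    calls = np.full((len(GLABROUS_VARIANTS), GLABROUS_N_WT + 1), REF, dtype=np.int8)
    rows = []
    for i, (pos, ref, alt, gene, effect, hgvs_p, _nlp, n_missing) in enumerate(
        GLABROUS_VARIANTS
    ):
        calls[i, :n_missing] = MISSING
        calls[i, GLABROUS_N_WT] = ALT
        first_alt = alt.split(",")[0].strip()
        ann = f"ANN={first_alt}|{effect}|MODIFIER|{gene}|||||||{hgvs_p}|"
        rows.append(("9", pos, ".", ref, alt, ".", ".", ann, "GT"))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    gen = GenotypeTable(variants=variants, calls=calls, sample_names=sample_names)
    return gen, phen


def glabrous_case_files(outdir, sample_order=None, phenotype_order=None) -> dict:
    """Write the glabrous benchmark as VCF + phenotype + GWAS-results files.

    ``sample_order`` / ``phenotype_order`` optionally permute the VCF sample
    columns and the phenotype rows (index arrays); the accuracy results are
    invariant to both, which makes the permutations a useful integrity
    check of the alignment step.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen, phen = glabrous_case_tables()
    if sample_order is not None:
        order = np.asarray(sample_order)
        gen = GenotypeTable(
            variants=gen.variants,
            calls=gen.calls[:, order],
            sample_names=[gen.sample_names[i] for i in order],
        )
    if phenotype_order is not None:
        order = np.asarray(phenotype_order)
        phen = PhenotypeTable(
            sample_names=[phen.sample_names[i] for i in order],
            values=phen.values[order],
        )
    pvalues = np.array([10.0 ** -nlp for (_p, _r, _a, _g, _e, _h, nlp, _m) in GLABROUS_VARIANTS])
    return {
        "vcf": write_vcf(gen, outdir / "glabrous.vcf"),
        "phenotype": export_phenotype(phen, str(outdir / "glabrous_phenotype")),
        "gwas_results": write_gwas_results(gen, pvalues, outdir / "glabrous_gwas.csv"),
    }
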