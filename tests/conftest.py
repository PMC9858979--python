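import numpy as np
import pandas as pd
import pytest

from gwacc import GenotypeTable, PhenotypeTable
from gwacc.genotype_io import VARIANT_COLUMNS


def make_genotype(calls, sample_names=None, chroms=None, positions=None,
                  refs=None, alts=None, infos=None) -> GenotypeTable:
    """Small-table builder used across the suite."""
    calls = np.asarray(calls, dtype=np.int8)
    n_var, n_samp = calls.shape
    sample_names = sample_names or [f"S{i + 1}" for i in range(n_samp)]
    chroms = chroms or ["1"] * n_var
    positions = positions or list(range(100, 100 + 10 * n_var, 10))
    refs = refs or ["A"] * n_var
    alts = alts or ["G"] * n_var
    infos = infos or ["."] * n_var
    variants = pd.DataFrame(
        {
            "#CHROM": chroms,
            "POS": positions,
            "ID": [f"v{i + 1}" for i in range(n_var)],
            "REF": refs,
            "ALT": alts,
            "QUAL": ".",
            "FILTER": ".",
            "INFO": infos,
            "FORMAT": "GT",
        },
        columns=VARIANT_COLUMNS,
    )
    return GenotypeTable(variants=variants, calls=calls, sample_names=sample_names)


def make_phenotype(values, sample_names=None) -> PhenotypeTable:
    values = np.asarray(values, dtype=np.int8)
    sample_names = sample_names or [f"S{i + 1}" for i in range(len(values))]
    return PhenotypeTable(sample_names=sample_names, values=values)


@pytest.fixture
def tiny_gen():
    # 3 variants x 5 samples covering REF/ALT/missing mixtures
    return make_genotype(
        [
            [0, 0, 1, 1, -2],
            [0, 1, 0, 1, 0],
            [-2, -2, 1, 0, 1],
        ]
    )


@pytest.fixture
def tiny_phen():
    return make_phenotype([0, 0, 1, 1, -2])
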