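import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gwacc
from gwacc import ClassCounts, GwaccError, accuracy_from_counts, count_classes
from gwacc.accuracy import STAT_COLUMNS

from conftest import make_genotype, make_phenotype


# --- independent oracle: literal per-sample tally + textbook formulas -------

def oracle_counts(calls, phen):
    nwr = nwa = nmr = nma = nw = nm = 0
    for c, p in zip(calls, phen):
        if p == 0:
            nw += 1
            if c == 0:
                nwr += 1
            elif c == 1:
                nwa += 1
        elif p == 1:
            nm += 1
            if c == 0:
                nmr += 1
            elif c == 1:
                nma += 1
    return nwr, nwa, nmr, nma, nw, nm


def oracle_stats(nwr, nwa, nmr, nma, nw, nm):
    def div(num, den):
        return 100.0 * num / den if den > 0 else math.nan

    acc_wt = div(nwr, nwr + nwa)
    acc_mut = div(nma, nmr + nma)
    acc_pes_wt = div(nwr, nw)
    acc_pes_mut = div(nma, nm)
    return {
        "Acc_WT": acc_wt,
        "Acc_MUT": acc_mut,
        "Avr_acc": (acc_wt + acc_mut) / 2,
        "Comb_acc_real": div(nwr + nma, nwr + nwa + nmr + nma),
        "Acc_pes_WT": acc_pes_wt,
        "Acc_pes_MUT": acc_pes_mut,
        "Avr_acc_pes": (acc_pes_wt + acc_pes_mut) / 2,
        "Comb_acc_pes": div(nwr + nma, nw + nm),
        "Missing_WT_gen": div(nw - nwr - nwa, nw),
        "Missing_MUT_gen": div(nm - nmr - nma, nm),
    }


def assert_close_or_both_nan(a, b, atol=1e-9):
    if math.isnan(b):
        assert math.isnan(a)
    else:
        assert a == pytest.approx(b, abs=atol)


# --- count_classes ----------------------------------------------------------

class TestCountClasses:
    def test_rare_phenotype_configuration(self):
        calls = np.array([0] * 294 + [-2] * 5 + [1], dtype=np.int8)
        phen = np.array([0] * 299 + [1], dtype=np.int8)
        c = count_classes(calls, phen)
        assert (c.n_wt_ref, c.n_wt_alt, c.n_mut_ref, c.n_mut_alt) == (294, 0, 0, 1)
        assert (c.n_wt, c.n_mut, c.n_all) == (299, 1, 300)

    def test_all_phenotypes_missing_gives_zero_counts(self):
        c = count_classes(np.array([0, 1, -2]), np.array([-2, -2, -2]))
        assert (c.n_wt, c.n_mut, c.n_all) == (0, 0, 0)

    def test_length_mismatch_errors(self):
        with pytest.raises(GwaccError, match="mismatch"):
            count_classes(np.array([0, 1]), np.array([0]))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.sampled_from([0, 1, -2]),
                              st.sampled_from([0, 1, -2])),
                    min_size=1, max_size=20))
    def test_matches_per_sample_loop(self, pairs):
        calls = np.array([c for c, _ in pairs], dtype=np.int8)
        phen = np.array([p for _, p in pairs], dtype=np.int8)
        c = count_classes(calls, phen)
        assert (c.n_wt_ref, c.n_wt_alt, c.n_mut_ref, c.n_mut_alt,
                c.n_wt, c.n_mut) == oracle_counts(calls, phen)


# --- accuracy_from_counts ---------------------------------------------------

class TestAccuracyFromCounts:
    def test_rare_phenotype_five_missing(self):
        r = accuracy_from_counts(ClassCounts(294, 0, 0, 1, 299, 1))
        assert round(r.avr_acc, 2) == 100
        assert round(r.acc_pes_wt, 2) == 98.33
        assert round(r.avr_acc_pes, 2) == 99.16
        assert round(r.comb_acc_real, 2) == 100
        assert round(r.comb_acc_pes, 2) == 98.33
        assert round(r.missing_wt_gen, 2) == 1.67

    def test_perfect_no_missing(self):
        r = accuracy_from_counts(ClassCounts(10, 0, 0, 10, 10, 10))
        for name in ("acc_wt", "acc_mut", "avr_acc", "comb_acc_real",
                     "acc_pes_wt", "acc_pes_mut", "avr_acc_pes", "comb_acc_pes"):
            assert getattr(r, name) == 100

    def test_perfect_anticorrespondence(self):
        r = accuracy_from_counts(ClassCounts(0, 10, 10, 0, 10, 10))
        assert r.avr_acc == 0
        assert r.comb_acc_real == 0

    def test_mixed_with_missing_hand_computed(self):
        r = accuracy_from_counts(ClassCounts(3, 1, 1, 3, 5, 5))
        assert r.acc_wt == 75 and r.acc_mut == 75 and r.avr_acc == 75
        assert r.comb_acc_real == 75
        assert r.acc_pes_wt == 60 and r.acc_pes_mut == 60
        assert r.avr_acc_pes == 60 and r.comb_acc_pes == 60

    def test_zero_denominator_is_nan_and_contagious(self):
        r = accuracy_from_counts(ClassCounts(5, 0, 0, 0, 5, 0))
        assert math.isnan(r.acc_mut) and math.isnan(r.acc_pes_mut)
        assert math.isnan(r.avr_acc) and math.isnan(r.avr_acc_pes)
        assert r.acc_wt == 100  # the defined component stays defined
        # the MUT class is empty, so only WT contributes to the combined stats
        assert r.comb_acc_real == 100 and r.comb_acc_pes == 100

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ClassCounts(6, 0, 0, 0, 5, 0)
        with pytest.raises(ValueError):
            ClassCounts(-1, 0, 0, 0, 5, 0)


# --- calc_accuracy: oracle equivalence and properties -----------------------

def random_cohort(rng, max_samples=50, max_variants=100):
    n_s = int(rng.integers(2, max_samples + 1))
    n_v = int(rng.integers(1, max_variants + 1))
    calls = rng.choice(np.array([0, 1, -2], dtype=np.int8), size=(n_v, n_s),
                       p=[0.45, 0.45, 0.10])
    phen = rng.choice(np.array([0, 1, -2], dtype=np.int8), size=n_s,
                      p=[0.45, 0.45, 0.10])
    return make_genotype(calls), make_phenotype(phen)


class TestCalcAccuracy:
    def test_vectorized_matches_literal_loop(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            gen, phen = random_cohort(rng, max_samples=30, max_variants=40)
            if (phen.values != -2).sum() == 0:
                continue
            acc = gwacc.calc_accuracy(gen, phen)
            for i in range(gen.n_variants):
                expected = oracle_stats(*oracle_counts(gen.calls[i], phen.values))
                for col in STAT_COLUMNS:
                    assert_close_or_both_nan(acc.data.loc[i, col], expected[col])

    def test_cal_ref_is_mut_swaps_allele_roles(self):
        rng = np.random.default_rng(5)
        gen, phen = random_cohort(rng, max_samples=20, max_variants=20)
        a = gwacc.calc_accuracy(gen, phen, cal="ref_is_wt")
        b = gwacc.calc_accuracy(gen, phen, cal="ref_is_mut")
        for i in range(gen.n_variants):
            nwr, nwa, nmr, nma, nw, nm = oracle_counts(gen.calls[i], phen.values)
            expected = oracle_stats(nwa, nwr, nma, nmr, nw, nm)
            for col in STAT_COLUMNS:
                assert_close_or_both_nan(b.data.loc[i, col], expected[col])
        # allele-swap antisymmetry where denominators are defined
        for col in ("Acc_WT", "Acc_MUT", "Avr_acc"):
            av, bv = a.data[col].to_numpy(), b.data[col].to_numpy()
            mask = np.isfinite(av) & np.isfinite(bv)
            np.testing.assert_allclose(av[mask] + bv[mask], 100.0)

    def test_phenotype_swap_antisymmetry(self):
        rng = np.random.default_rng(17)
        gen, phen = random_cohort(rng, max_samples=25, max_variants=30)
        swapped = make_phenotype(
            np.where(phen.values == -2, -2, 1 - phen.values),
            sample_names=phen.sample_names,
        )
        a = gwacc.calc_accuracy(gen, phen)
        b = gwacc.calc_accuracy(gen, swapped)
        av, bv = a.data["Avr_acc"].to_numpy(), b.data["Avr_acc"].to_numpy()
        mask = np.isfinite(av) & np.isfinite(bv)
        assert mask.any()
        np.testing.assert_allclose(av[mask] + bv[mask], 100.0)

    def test_no_missing_collapse(self):
        rng = np.random.default_rng(7)
        calls = rng.choice(np.array([0, 1], dtype=np.int8), size=(30, 20))
        phen = np.array([0] * 10 + [1] * 10, dtype=np.int8)
        acc = gwacc.calc_accuracy(make_genotype(calls), make_phenotype(phen))
        d = acc.data
        np.testing.assert_allclose(d["Acc_pes_WT"], d["Acc_WT"])
        np.testing.assert_allclose(d["Acc_pes_MUT"], d["Acc_MUT"])
        np.testing.assert_allclose(d["Avr_acc_pes"], d["Avr_acc"])
        np.testing.assert_allclose(d["Comb_acc_pes"], d["Comb_acc_real"])

    def test_pessimistic_never_exceeds_realistic(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            gen, phen = random_cohort(rng, max_samples=30, max_variants=30)
            if (phen.values != -2).sum() == 0:
                continue
            d = gwacc.calc_accuracy(gen, phen).data
            for pes, real in (("Acc_pes_WT", "Acc_WT"), ("Acc_pes_MUT", "Acc_MUT"),
                              ("Comb_acc_pes", "Comb_acc_real")):
                mask = np.isfinite(d[pes]) & np.isfinite(d[real])
                assert (d.loc[mask, pes] <= d.loc[mask, real] + 1e-9).all()

    def test_flip_reports_best_orientation(self):
        # unflipped Avr_acc 25 -> flip reports 75
        calls = np.array([[1, 1, 1, 0, 1, 0, 0, 0]], dtype=np.int8)
        phen = make_phenotype([0, 0, 0, 0, 1, 1, 1, 1])
        acc = gwacc.calc_accuracy(make_genotype(calls), phen, flip=False)
        assert acc.data.loc[0, "Avr_acc"] == 25
        flipped = gwacc.calc_accuracy(make_genotype(calls), phen, flip=True)
        assert flipped.data.loc[0, "Avr_acc"] == 75
        assert bool(flipped.data.loc[0, "Flipped"]) is True

    def test_flip_gives_avr_acc_at_least_50(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            gen, phen = random_cohort(rng, max_samples=30, max_variants=30)
            if (phen.values != -2).sum() == 0:
                continue
            d = gwacc.calc_accuracy(gen, phen, flip=True).data
            vals = d["Avr_acc"].to_numpy()
            assert (vals[np.isfinite(vals)] >= 50.0 - 1e-9).all()

    def test_flip_tie_keeps_unflipped(self):
        calls = np.array([[0, 1, 0, 1]], dtype=np.int8)  # Avr_acc 50 both ways
        phen = make_phenotype([0, 0, 1, 1])
        d = gwacc.calc_accuracy(make_genotype(calls), phen, flip=True).data
        assert d.loc[0, "Avr_acc"] == 50
        assert bool(d.loc[0, "Flipped"]) is False

    def test_missing_genotype_monotonicity(self):
        """Turning one WT REF call missing never helps pessimistic accuracy."""
        rng = np.random.default_rng(41)
        gen, phen = random_cohort(rng, max_samples=20, max_variants=20)
        base = gwacc.calc_accuracy(gen, phen).data
        wt_idx = np.flatnonzero(phen.values == 0)
        for i in range(gen.n_variants):
            ref_wt = [j for j in wt_idx if gen.calls[i, j] == 0]
            if not ref_wt:
                continue
            calls2 = gen.calls.copy()
            calls2[i, ref_wt[0]] = -2
            d2 = gwacc.calc_accuracy(make_genotype(calls2), phen).data
            assert d2.loc[i, "Acc_pes_WT"] <= base.loc[i, "Acc_pes_WT"] + 1e-9
            assert d2.loc[i, "Comb_acc_pes"] <= base.loc[i, "Comb_acc_pes"] + 1e-9
            assert_close_or_both_nan(d2.loc[i, "Acc_MUT"], base.loc[i, "Acc_MUT"])

    def test_unaligned_phenotype_is_aligned_internally(self):
        gen = make_genotype([[0, 1, 0]], sample_names=["A", "B", "C"])
        phen = make_phenotype([1, 0, 0], sample_names=["B", "C", "A"])
        acc = gwacc.calc_accuracy(gen, phen)
        c = count_classes(gen.calls[0], np.array([0, 1, 0]))
        assert acc.data.loc[0, "Acc_WT"] == accuracy_from_counts(c).acc_wt

    def test_zero_overlap_errors(self):
        gen = make_genotype([[0, 1]], sample_names=["A", "B"])
        phen = make_phenotype([0, 1], sample_names=["X", "Y"])
        with pytest.raises(GwaccError, match="overlap"), pytest.warns(UserWarning):
            gwacc.calc_accuracy(gen, phen)


# --- p-value joining and filtering ------------------------------------------

class TestAddPvalues:
    def _acc(self):
        gen = make_genotype([[0, 1], [1, 0], [0, 0]],
                            chroms=["1", "1", "2"], positions=[100, 200, 100])
        return gwacc.calc_accuracy(gen, make_phenotype([0, 1]))

    def test_join_and_log_identities(self, tmp_path):
        res = tmp_path / "gwas.csv"
        res.write_text("Chromosome,Position,P.value\nchr1,100,1.0\n1,200,0.01\n")
        acc = gwacc.add_pvalues(self._acc(), res)
        vals = acc.data["neg_log10_p"].tolist()
        assert vals[0] == pytest.approx(0.0)
        assert vals[1] == pytest.approx(2.0)
        assert math.isnan(vals[2])  # absent from results -> NA

    def test_shuffled_results_join_identically(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        a.write_text("Chromosome,Position,P.value\n1,100,0.5\n1,200,0.05\n2,100,0.2\n")
        b.write_text("Chromosome,Position,P.value\n2,100,0.2\n1,200,0.05\n1,100,0.5\n")
        va = gwacc.add_pvalues(self._acc(), a).data["neg_log10_p"]
        vb = gwacc.add_pvalues(self._acc(), b).data["neg_log10_p"]
        np.testing.assert_allclose(va, vb)

    def test_duplicates_keep_smallest_p(self, tmp_path):
        res = tmp_path / "gwas.csv"
        res.write_text("Chromosome,Position,P.value\n1,100,0.5\n1,100,0.001\n")
        with pytest.warns(UserWarning, match="duplicate"):
            acc = gwacc.add_pvalues(self._acc(), res)
        assert acc.data["neg_log10_p"].iloc[0] == pytest.approx(3.0)

    def test_neglog_input_taken_verbatim(self, tmp_path):
        res = tmp_path / "gwas.csv"
        res.write_text("Chromosome,Position,P.value\n1,100,7.25\n")
        acc = gwacc.add_pvalues(self._acc(), res, p_is_neglog=True)
        assert acc.data["neg_log10_p"].iloc[0] == 7.25

    def test_missing_column_lists_available(self, tmp_path):
        res = tmp_path / "gwas.csv"
        res.write_text("CHR,BP,P\n1,100,0.5\n")
        with pytest.raises(gwacc.ColumnError, match="CHR"):
            gwacc.add_pvalues(self._acc(), res, preset="gapit")
        ok = gwacc.add_pvalues(self._acc(), res, preset="plink")
        assert ok.data["neg_log10_p"].iloc[0] == pytest.approx(-math.log10(0.5))


class TestFilterAccuracy:
    def _acc_with_values(self, values):
        gen = make_genotype(np.zeros((len(values), 2), dtype=np.int8))
        acc = gwacc.calc_accuracy(gen, make_phenotype([0, 1]))
        acc.data["Avr_acc"] = values
        return acc

    def test_known_values_strict_threshold(self):
        acc = self._acc_with_values([90.0, 80.0, 70.0])
        kept = gwacc.filter_accuracy(acc, "Avr_acc", 80, keep="gt")
        assert kept.data["Avr_acc"].tolist() == [90.0]
        kept_ge = gwacc.filter_accuracy(acc, "Avr_acc", 80, keep="ge")
        assert kept_ge.data["Avr_acc"].tolist() == [90.0, 80.0]

    def test_partition_property(self):
        values = [90.0, 80.0, 70.0, math.nan, 50.0]
        acc = self._acc_with_values(values)
        t = 75.0
        n_pass = len(gwacc.filter_accuracy(acc, "Avr_acc", t, keep="gt"))
        n_le = sum(1 for v in values if not math.isnan(v) and v <= t)
        n_na = sum(1 for v in values if math.isnan(v))
        assert n_pass + n_le + n_na == len(values)

    def test_threshold_zero_keeps_all_defined(self):
        acc = self._acc_with_values([10.0, math.nan, 0.0])
        kept = gwacc.filter_accuracy(acc, "Avr_acc", 0, keep="ge")
        assert len(kept) == 2

    def test_unknown_metric_errors(self):
        acc = self._acc_with_values([50.0])
        with pytest.raises(gwacc.ColumnError):
            gwacc.filter_accuracy(acc, "NotAColumn", 50)
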