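"""Genotype-group summaries, QC filters, and the summary-statistic
meta-analysis Levene test against the individual-level oracle."""

import numpy as np
import pandas as pd
import pytest

import vqscreen as vq
from vqscreen import levene
from vqscreen.phenotype import PreparedPhenotype


def _prep(values):
    return PreparedPhenotype(np.asarray(values, float), {})


class TestCallGenotypes:
    def test_rounding_and_threshold(self):
        calls = vq.call_genotypes([1.9, 0.5, 0.0], threshold=0.4)
        assert list(calls) == [2, -1, 0]

    def test_integer_dosages_pass_through(self):
        calls = vq.call_genotypes(np.array([0, 1, 2, 1], dtype=np.int8))
        assert list(calls) == [0, 1, 2, 1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vq.call_genotypes([0.5, 2.3])


class TestSummaries:
    def test_twelve_individual_hand_computation(self):
        y = np.array([0.2, -1.0, 0.5, 1.5, -0.5, 0.0, 2.0, -2.0, 1.0, 0.3, -0.3, 0.8])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 2, 2, 2])
        s = vq.summarize_groups(g.astype(float), _prep(y), "c1")
        for cls in (0, 1, 2):
            sub = y[g == cls]
            z = np.abs(sub - sub.mean())
            assert s.n[cls] == len(sub)
            assert s.mean_z[cls] == pytest.approx(z.mean())
            assert s.var_z[cls] == pytest.approx(z.var(ddof=1))

    def test_singleton_group_variance_undefined(self):
        s = vq.summarize_groups(np.array([0.0, 0.0, 1.0, 2.0]),
                                _prep([1.0, 2.0, 3.0, 4.0]), "c1")
        assert s.n[2] == 1 and np.isnan(s.var_z[2]) and not np.isnan(s.mean_z[2])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        g = rng.integers(0, 3, size=40).astype(float)
        a = vq.summarize_groups(g, _prep(y), "c1")
        perm = rng.permutation(40)
        b = vq.summarize_groups(g[perm], _prep(y[perm]), "c1")
        np.testing.assert_allclose(a.mean_z, b.mean_z)
        np.testing.assert_allclose(a.var_z, b.var_z)

    def test_matrix_summarizer_matches_single_snp_path(self, small_cohort, tmp_path):
        prep = vq.prepare_trait(small_cohort.phenotype)
        table = vq.summarize_cohort(small_cohort.genotypes, prep, "c1",
                                    small_cohort.snp_meta)
        j = 7
        s = vq.summarize_groups(small_cohort.genotypes[:, j].astype(float), prep, "c1")
        row = table.iloc[j]
        np.testing.assert_allclose(
            row[["meanZ0", "meanZ1", "meanZ2"]].to_numpy(float), s.mean_z)
        np.testing.assert_allclose(
            row[["varZ0", "varZ1", "varZ2"]].to_numpy(float), s.var_z)
        # exchange-format roundtrip is lossless at 10 significant digits
        path = tmp_path / "summ.tsv"
        levene.write_group_summaries(table, path)
        back = levene.read_group_summaries(path)
        np.testing.assert_allclose(back["meanZ1"], table["meanZ1"], rtol=1e-9)


class TestHWE:
    def test_exact_proportions_give_p_one(self):
        assert vq.hwe_test(8100, 1800, 100) == pytest.approx(1.0)

    def test_all_heterozygote_chi_square_equals_n(self):
        # chi2 = n in closed form; far below any usual threshold for n >= 30
        from scipy.stats import chi2
        assert vq.hwe_test(0, 30, 0) == pytest.approx(chi2.sf(30, 1))
        assert vq.hwe_test(0, 100, 0) < 1e-6

    def test_monomorphic_convention(self):
        assert vq.hwe_test(0, 0, 50) == 1.0
        assert vq.hwe_test(50, 0, 0) == 1.0


def _summary_row(snp="snp1", cohort="c1", n=(400, 200, 40), mz=(0.8, 0.8, 0.8),
                 vz=(0.3, 0.3, 0.3), eaf=0.25, info=1.0, callrate=1.0):
    return {
        "snp_id": snp, "cohort": cohort, "ea": "A", "oa": "G", "eaf": eaf,
        "info": info, "callrate": callrate,
        "n0": n[0], "n1": n[1], "n2": n[2],
        "meanZ0": mz[0], "meanZ1": mz[1], "meanZ2": mz[2],
        "varZ0": vz[0], "varZ1": vz[1], "varZ2": vz[2],
    }


class TestQC:
    def test_low_maf_excluded(self):
        df = pd.DataFrame([_summary_row(eaf=0.005)])
        kept, excl = vq.qc_filter(df)
        assert len(kept) == 0 and excl["reason"].iloc[0] == "MAF"

    def test_small_group_excluded(self):
        df = pd.DataFrame([_summary_row(n=(400, 200, 29), eaf=0.3)])
        kept, excl = vq.qc_filter(df)
        assert excl["reason"].iloc[0] == "MIN_GROUP_N"

    def test_most_permissive_is_identity(self):
        df = pd.DataFrame([_summary_row(), _summary_row(snp="snp2", eaf=0.005),
                           _summary_row(snp="snp3", n=(5, 3, 2))])
        kept, excl = vq.qc_filter(df, levene.QCThresholds.most_permissive())
        assert len(kept) == 3 and len(excl) == 0

    def test_hwe_info_and_callrate_filters(self):
        rows = [
            _summary_row(snp="hwe_bad", n=(300, 0, 300)),
            _summary_row(snp="info_bad", info=0.1),
            _summary_row(snp="cr_bad", callrate=0.5),
            _summary_row(snp="ok"),
        ]
        kept, excl = vq.qc_filter(pd.DataFrame(rows))
        reasons = dict(zip(excl["snp_id"], excl["reason"]))
        assert reasons == {"hwe_bad": "HWE", "info_bad": "INFO", "cr_bad": "CALLRATE"}
        assert list(kept["snp_id"]) == ["ok"]

    def test_permissive_mode_tolerates_absent_group(self):
        df = pd.DataFrame([_summary_row(n=(400, 100, 0), eaf=0.1)])
        strict, _ = vq.qc_filter(df)
        loose, _ = vq.qc_filter(
            df, levene.QCThresholds(strict_three_groups=False))
        assert len(strict) == 0 and len(loose) == 1


class TestLeveneDirect:
    def test_finite_hand_computed_statistic(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 4.0, 6.0, 1.0, 5.0, 9.0])
        g = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        w, p = vq.levene_direct(_prep(y), g)
        # brute-force arithmetic oracle
        z = np.concatenate([np.abs(y[g == c] - y[g == c].mean()) for c in (0, 1, 2)])
        gz = np.repeat([0, 1, 2], 3)
        zbars = np.array([z[gz == c].mean() for c in (0, 1, 2)])
        ssb = sum(3 * (zb - z.mean()) ** 2 for zb in zbars)
        ssw = sum(((z[gz == c] - zbars[c]) ** 2).sum() for c in (0, 1, 2))
        w_expected = (9 - 3) / (3 - 1) * ssb / ssw
        assert w == pytest.approx(w_expected, rel=1e-12)

    def test_perfect_separation_underflows_not_errors(self):
        # deviations are constant within groups: zero denominator, P floored
        y = np.array([1.0, 1.0, 1.0, 0.0, 2.0, -1.0, 3.0])
        g = np.array([0, 0, 0, 1, 1, 2, 2])
        with np.errstate(divide="ignore", invalid="ignore"):
            w, p = vq.levene_direct(_prep(y), g)
        assert not np.isfinite(w) or w > 1e10
        assert p == levene.P_FLOOR

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        g = rng.integers(0, 3, 60)
        w1, _ = vq.levene_direct(_prep(y), g)
        w2, _ = vq.levene_direct(_prep(y * 3.7), g)
        assert w1 == pytest.approx(w2, rel=1e-12)


class TestMetaLevene:
    def _random_dataset(self, rng, n=None):
        n = n or rng.integers(90, 600)
        maf = rng.uniform(0.15, 0.5)
        g = rng.binomial(2, maf, n).astype(float)
        y = rng.normal(0, 1 + 0.3 * g, n)  # heteroskedastic to vary W
        return g, _prep(y)

    def test_single_cohort_reproduces_classical_levene(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            g, prep = self._random_dataset(rng)
            s = vq.summarize_groups(g, prep, "c1")
            res = vq.meta_levene([s])
            w, p = vq.levene_direct(prep, g)
            assert abs(res.L - w) / max(w, 1.0) < 1e-8
            assert res.p_v == pytest.approx(p, rel=1e-6)
            assert res.df2 == len(g) - 3

    def test_equal_group_means_give_zero_statistic(self):
        df = pd.DataFrame([
            _summary_row(cohort="c1", mz=(0.7, 0.7, 0.7)),
            _summary_row(cohort="c2", mz=(0.7, 0.7, 0.7), n=(100, 80, 60)),
        ])
        res = vq.meta_levene(df)
        assert res.L == pytest.approx(0.0, abs=1e-12)
        assert res.p_v == pytest.approx(1.0)

    def test_duplicated_cohorts_match_pooled_individuals(self):
        rng = np.random.default_rng(11)
        g, prep = self._random_dataset(rng, n=200)
        s1 = vq.summarize_groups(g, prep, "c1")
        s2 = vq.summarize_groups(g, prep, "c2")
        res = vq.meta_levene([s1, s2])
        pooled = _prep(np.concatenate([prep.values, prep.values]))
        w, _ = vq.levene_direct(pooled, np.concatenate([g, g]))
        assert res.L == pytest.approx(w, rel=1e-10)
        assert res.N == 400

    def test_weight_normalization(self):
        rng = np.random.default_rng(12)
        summaries = []
        for c in range(3):
            g, prep = self._random_dataset(rng, n=150)
            summaries.append(vq.summarize_groups(g, prep, f"c{c}"))
        res = vq.meta_levene(summaries)
        np.testing.assert_allclose(res.weights["omega"].sum(axis=0), 1.0, atol=1e-12)
        assert res.weights["gamma"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_cohort_order_invariance(self):
        rng = np.random.default_rng(13)
        summaries = [vq.summarize_groups(*self._random_dataset(rng, n=120), f"c{c}")
                     for c in range(4)]
        L1 = vq.meta_levene(summaries).L
        L2 = vq.meta_levene(summaries[::-1]).L
        assert abs(L1 - L2) < 1e-12 * max(L1, 1)

    def test_inflating_one_group_dispersion_increases_statistic(self):
        # scaling group-2 trait values about their mean scales that group's
        # Z up, pushing the between-group Z dispersion and L up with it
        rng = np.random.default_rng(14)
        g = rng.integers(0, 3, 400).astype(float)
        y = rng.normal(size=400)
        stats_seq = []
        for c in (1.0, 1.5, 2.5, 4.0):
            y2 = y.copy()
            sel = g == 2
            y2[sel] = y[sel].mean() + c * (y[sel] - y[sel].mean())
            res = vq.meta_levene([vq.summarize_groups(g, _prep(y2), "c1")])
            stats_seq.append(res.L)
        assert all(b > a for a, b in zip(stats_seq, stats_seq[1:]))

    def test_fewer_than_three_pooled_groups_skipped(self):
        df = pd.DataFrame([_summary_row(n=(300, 100, 0))])
        res = vq.meta_levene(df)
        assert res.reason == "NO_3_GROUPS" and np.isnan(res.L)

    def test_table_and_single_snp_paths_agree(self, small_cohort):
        prep = vq.prepare_trait(small_cohort.phenotype)
        summ = vq.summarize_cohort(small_cohort.genotypes, prep, "c1",
                                   small_cohort.snp_meta)
        table = vq.meta_levene_table(summ)
        j = 5
        one = vq.meta_levene(summ.iloc[[j]])
        assert table["L"].iloc[j] == pytest.approx(one.L, rel=1e-12)


class TestHarmonization:
    def _ref(self):
        return pd.DataFrame({"snp_id": ["snp1"], "ea": ["A"], "oa": ["G"],
                             "eaf": [0.2]})

    def test_swapped_alleles_flip_group_order(self):
        row = _summary_row(n=(10, 20, 70), mz=(0.1, 0.2, 0.3), vz=(1.0, 2.0, 3.0),
                           eaf=0.8)
        row["ea"], row["oa"] = "G", "A"
        kept, log = vq.harmonize_alleles(pd.DataFrame([row]), self._ref())
        assert len(log) == 0
        out = kept.iloc[0]
        assert (out["n0"], out["n1"], out["n2"]) == (70, 20, 10)
        assert out["eaf"] == pytest.approx(0.2)
        assert (out["meanZ0"], out["varZ0"]) == (0.3, 3.0)

    def test_ambiguous_near_half_frequency_dropped(self):
        ref = pd.DataFrame({"snp_id": ["snp1"], "ea": ["A"], "oa": ["T"],
                            "eaf": [0.45]})
        row = _summary_row(eaf=0.55)
        row["ea"], row["oa"] = "A", "T"
        kept, log = vq.harmonize_alleles(pd.DataFrame([row]), ref)
        assert len(kept) == 0 and log["reason"].iloc[0] == "STRAND_AMBIGUOUS"

    def test_ambiguous_resolved_by_clear_frequency(self):
        ref = pd.DataFrame({"snp_id": ["snp1"], "ea": ["A"], "oa": ["T"],
                            "eaf": [0.2]})
        row = _summary_row(eaf=0.8, n=(5, 30, 65))
        row["ea"], row["oa"] = "A", "T"
        kept, _ = vq.harmonize_alleles(pd.DataFrame([row]), ref)
        assert kept.iloc[0]["eaf"] == pytest.approx(0.2)
        assert kept.iloc[0]["n0"] == 65  # flipped


class TestExchangeValidation:
    def test_negative_count_rejected(self, tmp_path):
        df = pd.DataFrame([_summary_row()])
        df.loc[0, "n0"] = -1
        p = tmp_path / "bad.tsv"
        levene.write_group_summaries(df, p)
        with pytest.raises(ValueError, match="negative"):
            levene.read_group_summaries(p)

    def test_variance_with_tiny_group_rejected(self, tmp_path):
        df = pd.DataFrame([_summary_row(n=(1, 200, 200))])
        p = tmp_path / "bad.tsv"
        levene.write_group_summaries(df, p)
        with pytest.raises(ValueError, match="n < 2"):
            levene.read_group_summaries(p)
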