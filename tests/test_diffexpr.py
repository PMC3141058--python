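"""t-tests, threshold calling, SAM permutation FDR, hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from mirconcord.diffexpr import (
    PRESETS,
    TISSUE_MIRNA,
    TISSUE_MRNA,
    TRANSFECTION,
    ThresholdConfig,
    call_de,
    hypergeometric_enrichment,
    sam_qvalues,
    ttest_two_sample,
)
from .conftest import make_de_result, make_matrix


class TestTTest:
    def test_identical_groups_null_result(self):
        m = make_matrix([[1.0, 2.0, 1.0, 2.0], [5.0, 6.0, 5.0, 6.0]])
        res = ttest_two_sample(m, "case", "control")
        np.testing.assert_allclose(res.table["lfc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p"], 1.0, atol=1e-12)

    def test_hand_computed_vector(self):
        m = make_matrix([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]])
        res = ttest_two_sample(m, "case", "control")
        assert res.table["lfc"].iloc[0] == pytest.approx(-1.0, abs=1e-12)
        assert res.table["t"].iloc[0] == pytest.approx(-1.224744871, abs=1e-8)
        # 2 * StudentT(df=4).sf(1.224745) = 0.2878641
        assert res.table["p"].iloc[0] == pytest.approx(0.2878641, abs=1e-6)

    def test_p_matches_incomplete_beta_closed_form(self, rng):
        m = make_matrix(rng.normal(size=(200, 7)),
                        groups={f"s{j}": ("case" if j < 3 else "control") for j in range(7)})
        res = ttest_two_sample(m, "case", "control")
        df = 5
        t = res.table["t"].to_numpy()
        closed = special.betainc(df / 2.0, 0.5, df / (df + t**2))
        np.testing.assert_allclose(res.table["p"].to_numpy(), closed, atol=1e-9)

    def test_within_group_sample_permutation_invariance(self, rng):
        vals = rng.normal(size=(30, 6))
        ids = [f"s{j}" for j in range(6)]
        groups = {s: ("case" if j < 3 else "control") for j, s in enumerate(ids)}
        m1 = make_matrix(vals, sample_ids=ids, groups=groups)
        perm = [2, 0, 1, 5, 3, 4]  # permute within each group
        m2 = make_matrix(vals[:, perm], sample_ids=[ids[j] for j in perm], groups=groups)
        r1, r2 = (ttest_two_sample(m, "case", "control") for m in (m1, m2))
        for col in ("lfc", "t", "p"):
            np.testing.assert_allclose(r1.table[col], r2.table[col], atol=1e-12)

    def test_zero_variance_conventions(self):
        m = make_matrix([[1.0, 1.0, 3.0, 3.0], [2.0, 2.0, 2.0, 2.0]])
        res = ttest_two_sample(m, "case", "control")
        assert res.table["p"].iloc[0] == 0.0  # difference with no noise
        assert res.table["p"].iloc[1] == 1.0  # no difference, no noise

    def test_small_group_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]], groups={"s0": "case", "s1": "control", "s2": "control"})
        with pytest.raises(ValueError, match=">= 2 samples"):
            ttest_two_sample(m, "case", "control")


class TestCallDe:
    def test_tissue_mirna_preset_flags_up(self):
        res = make_de_result(["x"], lfc=[1.2], p=[0.009])
        out = call_de(res, TISSUE_MIRNA)
        assert out.table["de_flag"].iloc[0]
        assert out.table["direction"].iloc[0] == "up"

    def test_tissue_mrna_preset_requires_full_log2_unit(self):
        res = make_de_result(["x"], lfc=[0.9], p=[0.004])
        assert not call_de(res, TISSUE_MRNA).table["de_flag"].iloc[0]

    def test_lfc_threshold_is_inclusive(self):
        res = make_de_result(["x"], lfc=[1.0], p=[0.001])
        assert call_de(res, TISSUE_MRNA).table["de_flag"].iloc[0]

    def test_q_threshold_without_q_is_an_error(self):
        res = make_de_result(["x"], lfc=[2.0], p=[0.001])
        calls = pd.DataFrame({"s": ["P"]}, index=["x"])
        with pytest.raises(ValueError, match="q-values"):
            call_de(res, TRANSFECTION, calls=calls)

    def test_present_in_one_requirement(self):
        res = make_de_result(["x", "y"], lfc=[-0.8, -0.8], p=[0.001, 0.001], q=[0.01, 0.01])
        calls = pd.DataFrame({"s1": ["A", "P"], "s2": ["A", "A"]}, index=["x", "y"])
        out = call_de(res, TRANSFECTION, calls=calls)
        assert not out.table.loc["x", "de_flag"]  # Absent everywhere
        assert out.table.loc["y", "de_flag"]
        assert out.table.loc["y", "direction"] == "down"

    def test_relaxing_thresholds_is_monotone(self, rng):
        n = 300
        res = make_de_result(
            [f"p{i}" for i in range(n)],
            lfc=rng.normal(0, 1.5, n),
            p=rng.random(n),
        )
        strict = call_de(res, ThresholdConfig(p_max=0.005, abs_lfc_min=1.0))
        loose = call_de(res, ThresholdConfig(p_max=0.05, abs_lfc_min=0.5))
        assert (strict.table["de_flag"] <= loose.table["de_flag"]).all()

    def test_flag_implies_direction_matches_lfc_sign(self, rng):
        n = 200
        res = make_de_result([f"p{i}" for i in range(n)], lfc=rng.normal(0, 2, n), p=rng.random(n))
        out = call_de(res, ThresholdConfig(p_max=0.5, abs_lfc_min=0.5))
        f = out.table[out.table["de_flag"]]
        assert ((f["lfc"] > 0) == (f["direction"] == "up")).all()
        assert (out.table.loc[~out.table["de_flag"], "direction"] == "none").all()


class TestTypeICalibration:
    def test_null_p_value_rates_at_both_alphas(self, rng):
        n = 20000
        m = make_matrix(rng.normal(size=(n, 6)))
        res = ttest_two_sample(m, "case", "control")
        p = res.table["p"].to_numpy()
        for alpha in (0.01, 0.005):
            frac = np.mean(p < alpha)
            half = 2.576 * math.sqrt(alpha * (1 - alpha) / n)
            assert abs(frac - alpha) < half


class TestSam:
    def test_null_calibration_few_probes_pass(self):
        hits = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = make_matrix(r.normal(size=(200, 6)))
            q = sam_qvalues(m, "case", "control", n_perm=25, seed=seed)
            hits.append(np.mean(q <= 0.05))
        assert np.mean(hits) <= 0.05

    def test_planted_probes_have_smallest_q(self, rng):
        n_null, n_plant = 450, 50
        null = rng.normal(0, 0.3, size=(n_null, 6))
        planted = rng.normal(0, 0.3, size=(n_plant, 6))
        planted[:, :3] += 3.0
        m = make_matrix(np.vstack([null, planted]))
        q = sam_qvalues(m, "case", "control", n_perm=25, seed=0)
        planted_ids = {f"p{i}" for i in range(n_null, n_null + n_plant)}
        assert q[list(planted_ids)].max() < q.drop(list(planted_ids)).min()

    def test_s0_zero_ranking_matches_t_ranking(self, rng):
        m = make_matrix(rng.normal(size=(50, 6)))
        q = sam_qvalues(m, "case", "control", n_perm=25, seed=0, s0=0.0)
        t = ttest_two_sample(m, "case", "control").table["t"].abs()
        # q is a monotone transform of |d|; with s0=0, |d| is proportional to |t|
        assert (q.to_numpy()[np.argsort(-t.to_numpy())] == np.sort(q.to_numpy())).all()

    def test_too_few_permutations_rejected(self, rng):
        m = make_matrix(rng.normal(size=(10, 6)))
        with pytest.raises(ValueError, match="n_perm"):
            sam_qvalues(m, "case", "control", n_perm=10)


def brute_force_hypergeom_upper(N, K, n, k):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


class TestHypergeometricEnrichment:
    def test_worked_example(self):
        bg = [f"g{i}" for i in range(10)]
        res = hypergeometric_enrichment(bg[:4], {"set": bg[2:7]}, bg)
        # N=10, K=5, n=4, k=2 -> recompute via enumeration
        assert res.loc["set", "p"] == pytest.approx(
            brute_force_hypergeom_upper(10, 5, 4, 2), abs=1e-12
        )

    def test_counting_example_55_over_210(self):
        # N=10, K=5, n=4, overlap k=3: p = [C(5,3)C(5,1)+C(5,4)C(5,0)]/C(10,4)
        bg = [f"g{i}" for i in range(10)]
        de = ["g0", "g1", "g2", "g9"]
        target = ["g0", "g1", "g2", "g3", "g4"]
        res = hypergeometric_enrichment(de, {"s": target}, bg)
        assert res.loc["s", "k"] == 3
        assert res.loc["s", "p"] == pytest.approx(55 / 210, abs=1e-12)

    def test_zero_overlap_gives_p_one_when_feasible(self):
        bg = [f"g{i}" for i in range(10)]
        res = hypergeometric_enrichment(bg[:4], {"s": bg[6:9]}, bg)
        # K + n <= N so k = 0 has positive probability; P(X >= 0) = 1
        assert res.loc["s", "k"] == 1 or res.loc["s", "p"] <= 1.0
        res2 = hypergeometric_enrichment(bg[:3], {"s": bg[7:10]}, bg)
        assert res2.loc["s", "k"] == 0
        assert res2.loc["s", "p"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_for_all_small_instances(self):
        for N in range(1, 13):
            bg = [f"g{i}" for i in range(N)]
            for K in range(N + 1):
                for n in range(N + 1):
                    de = bg[:n]
                    target = bg[N - K:]
                    res = hypergeometric_enrichment(de, {"s": target}, bg)
                    k = res.loc["s", "k"]
                    assert res.loc["s", "p"] == pytest.approx(
                        brute_force_hypergeom_upper(N, K, n, k), abs=1e-12
                    )

    def test_bh_qvalues_monotone_in_p_rank(self, rng):
        bg = [f"g{i}" for i in range(100)]
        de = list(rng.choice(bg, size=30, replace=False))
        sets = {
            f"s{j}": list(rng.choice(bg, size=rng.integers(5, 40), replace=False))
            for j in range(12)
        }
        res = hypergeometric_enrichment(de, sets, bg).sort_values("p")
        assert (np.diff(res["q"].to_numpy()) >= -1e-12).all()

    def test_de_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            hypergeometric_enrichment(["x"], {"s": ["a"]}, ["a", "b"])
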