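"""IC/NC/PC classification, fraction aggregation, validated-target logic."""

import numpy as np
import pandas as pd
import pytest

from mirconcord.concordance import (
    FractionSummary,
    aggregate_over_methods,
    average_across_methods,
    classify_concordance,
    cross_tabulate_validated,
    derive_validated_targets,
    evaluate_recovery,
    round_half_up,
    summarize_fractions,
)
from mirconcord.diffexpr import TISSUE_MRNA, TRANSFECTION, ThresholdConfig
from mirconcord.target_maps import ProbeTargetMap
from .conftest import make_de_result


def probe_map(pairs):
    return ProbeTargetMap(
        pd.DataFrame(
            [{"mirna": m, "probeset": p, "gene": p.replace("_at", "")} for m, p in pairs]
        )
    )


@pytest.fixture
def simple_case():
    """One up-miRNA with one clear IC target, one NC, one PC."""
    targets = probe_map(
        [("hsa-miR-7", "A_at"), ("hsa-miR-7", "B_at"), ("hsa-miR-7", "C_at")]
    )
    mrna_de = make_de_result(
        ["A_at", "B_at", "C_at"],
        lfc=[-1.5, -2.0, 2.0],
        p=[0.001, 0.20, 0.001],
    )
    return targets, {"hsa-miR-7": "up"}, mrna_de


class TestClassification:
    def test_three_canonical_outcomes(self, simple_case):
        targets, dirs, mrna_de = simple_case
        table = classify_concordance(targets, dirs, mrna_de, TISSUE_MRNA)
        by_probe = dict(zip(table.records["probeset"], table.records["cls"]))
        assert by_probe == {"A_at": "IC", "B_at": "NC", "C_at": "PC"}

    def test_class_counts_sum_to_records(self, simple_case):
        targets, dirs, mrna_de = simple_case
        table = classify_concordance(targets, dirs, mrna_de, TISSUE_MRNA)
        counts = table.class_counts()
        assert int(counts["total"].sum()) == len(table)

    def test_direction_flip_swaps_ic_and_pc_exactly(self, rng):
        n = 120
        probes = [f"g{i}_at" for i in range(n)]
        pairs = [(f"hsa-miR-{i % 4}", p) for i, p in enumerate(probes)]
        mrna_de = make_de_result(
            probes, lfc=rng.normal(0, 1.5, n), p=rng.random(n) * 0.02
        )
        dirs = {f"hsa-miR-{k}": ("up" if k % 2 else "down") for k in range(4)}
        flipped = {m: ("down" if d == "up" else "up") for m, d in dirs.items()}
        t1 = classify_concordance(probe_map(pairs), dirs, mrna_de, TISSUE_MRNA)
        t2 = classify_concordance(probe_map(pairs), flipped, mrna_de, TISSUE_MRNA)
        c1, c2 = t1.records["cls"].value_counts(), t2.records["cls"].value_counts()
        assert c1.get("IC", 0) == c2.get("PC", 0)
        assert c1.get("PC", 0) == c2.get("IC", 0)
        assert c1.get("NC", 0) == c2.get("NC", 0)

    def test_restricting_map_preserves_retained_classes(self, simple_case, rng):
        targets, dirs, mrna_de = simple_case
        full = classify_concordance(targets, dirs, mrna_de, TISSUE_MRNA)
        sub = ProbeTargetMap(targets.pairs.iloc[[0, 2]])
        part = classify_concordance(sub, dirs, mrna_de, TISSUE_MRNA)
        merged = part.records.merge(full.records, on=["mirna", "probeset"], suffixes=("_sub", "_full"))
        assert (merged["cls_sub"] == merged["cls_full"]).all()

    def test_missing_mirna_direction_is_an_error(self, simple_case):
        targets, _, mrna_de = simple_case
        with pytest.raises(ValueError, match="hsa-miR-7"):
            classify_concordance(targets, {}, mrna_de, TISSUE_MRNA)


class TestSummaries:
    def test_single_mirna_half_ic_half_nc(self):
        targets = probe_map([("hsa-miR-1", "A_at"), ("hsa-miR-1", "B_at")])
        mrna_de = make_de_result(["A_at", "B_at"], lfc=[-2.0, 0.1], p=[0.001, 0.8])
        table = classify_concordance(targets, {"hsa-miR-1": "up"}, mrna_de, TISSUE_MRNA)
        summary = summarize_fractions(table)
        row = summary.per_mirna.loc["hsa-miR-1"]
        assert (row["pct_IC"], row["pct_NC"], row["pct_PC"]) == (50.0, 50.0, 0.0)

    def test_percentages_sum_to_100_per_mirna(self, rng):
        n = 200
        probes = [f"g{i}_at" for i in range(n)]
        pairs = [(f"hsa-miR-{i % 5}", p) for i, p in enumerate(probes)]
        mrna_de = make_de_result(probes, lfc=rng.normal(0, 1.5, n), p=rng.random(n))
        dirs = {f"hsa-miR-{k}": ("up" if k < 3 else "down") for k in range(5)}
        summary = summarize_fractions(
            classify_concordance(probe_map(pairs), dirs, mrna_de, TISSUE_MRNA)
        )
        sums = summary.per_mirna[["pct_IC", "pct_NC", "pct_PC"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)
        rounded = summary.to_table()
        agg_sums = rounded[["pct_IC", "pct_NC", "pct_PC"]].sum(axis=1)
        assert (abs(agg_sums - 100.0) <= 0.02 + 1e-9).all()

    def test_overall_is_mean_of_group_means_not_pooled(self):
        per = pd.DataFrame(
            {
                "total": [100, 100, 100],
                "pct_IC": [10.0, 20.0, 40.0],
                "pct_NC": [80.0, 70.0, 50.0],
                "pct_PC": [10.0, 10.0, 10.0],
                "mirna_direction": ["up", "up", "down"],
            },
            index=["a", "b", "c"],
        )
        s = FractionSummary.from_per_mirna(per)
        assert s.group_means["up"]["IC"] == pytest.approx(15.0)
        assert s.overall["IC"] == pytest.approx((15.0 + 40.0) / 2)  # not 70/3

    def test_empty_table_is_an_error(self):
        targets = probe_map([("hsa-miR-1", "Z_at")])
        mrna_de = make_de_result(["Y_at"], lfc=[0.0], p=[1.0])
        table = classify_concordance(targets, {"hsa-miR-1": "up"}, mrna_de, TISSUE_MRNA)
        with pytest.raises(ValueError, match="empty"):
            summarize_fractions(table)

    def test_method_average_is_mean_of_overalls(self):
        a = {"IC": 11.16, "NC": 78.56, "PC": 10.28}
        b = {"IC": 10.37, "NC": 79.34, "PC": 10.29}
        c = {"IC": 9.41, "NC": 80.48, "PC": 10.11}
        avg = average_across_methods({"M": a, "TS": b, "PT": c})
        assert round_half_up(avg["IC"]) == 10.31
        assert round_half_up(avg["NC"]) == 79.46
        identical = average_across_methods({"x": a, "y": a})
        assert identical == pytest.approx(a)

    def test_aggregate_over_methods_rule(self):
        per, overall = aggregate_over_methods({"m1": [10.0, 20.0], "m2": [0.0, 0.0]})
        assert per == {"m1": 15.0, "m2": 0.0}
        assert overall == 7.5


class TestValidatedTargets:
    def make_transfection(self):
        probes = ["A_at", "B_at", "C_at", "D_at"]
        return make_de_result(
            probes,
            lfc=[-0.6, 0.6, -0.6, -2.0],
            p=[0.001] * 4,
            q=[0.02, 0.02, 0.30, 0.02],
        )

    def test_down_regulated_predicted_targets_validate(self):
        de = self.make_transfection()
        predicted = probe_map(
            [("hsa-miR-7", "A_at"), ("hsa-miR-7", "B_at"), ("hsa-miR-7", "C_at")]
        )
        calls = pd.DataFrame(
            {"s1": ["P"] * 4, "s2": ["P"] * 4},
            index=["A_at", "B_at", "C_at", "D_at"],
        )
        v = derive_validated_targets(de, predicted, TRANSFECTION, "hsa-miR-7", calls=calls)
        # A: down + q ok -> validated; B: up -> no; C: q too high -> no;
        # D: down but not predicted -> absent
        assert set(v.pairs["probeset"]) == {"A_at"}

    def test_unpredicted_mirna_is_an_error(self):
        de = self.make_transfection()
        predicted = probe_map([("hsa-miR-7", "A_at")])
        with pytest.raises(ValueError, match="miR-128"):
            derive_validated_targets(de, predicted, TRANSFECTION, "hsa-miR-128")

    def test_cross_tabulation_aggregates_methods_then_mirnas(self):
        tissue_de = make_de_result(
            ["A_at", "B_at", "C_at", "D_at"],
            lfc=[-2.0, 0.0, 2.0, -1.5],
            p=[0.001, 1.0, 0.001, 0.001],
        )
        validated = {
            "hsa-miR-7": {
                "M": probe_map([("hsa-miR-7", "A_at"), ("hsa-miR-7", "B_at")]),
                "TS": probe_map([("hsa-miR-7", "B_at")]),
            },
            "hsa-miR-128": {
                "M": probe_map([("hsa-miR-128", "D_at")]),
            },
        }
        dirs = {"hsa-miR-7": "up", "hsa-miR-128": "up"}
        out = cross_tabulate_validated(validated, dirs, tissue_de, TISSUE_MRNA)
        # miR-7: M -> 50% IC, TS -> 0% IC; mean 25%; miR-128: 100% IC
        m7 = out[(out["miRNA"] == "hsa-miR-7") & (out["method"] == "all methods (mean)")]
        assert m7["pct_IC"].iloc[0] == pytest.approx(25.0)
        overall = out[out["miRNA"] == "overall"]
        assert overall["pct_IC"].iloc[0] == pytest.approx((25.0 + 100.0) / 2)


class TestRecovery:
    def test_perfect_classification_identity_confusion(self, simple_case):
        targets, dirs, mrna_de = simple_case
        table = classify_concordance(targets, dirs, mrna_de, TISSUE_MRNA)
        truth = {("hsa-miR-7", "A"): "IC", ("hsa-miR-7", "B"): "NC", ("hsa-miR-7", "C"): "PC"}
        rec = evaluate_recovery(table, truth)
        assert (np.diag(rec["confusion"].to_numpy()) == 1).all()
        assert rec["confusion"].to_numpy().sum() == 3
        assert all(v == 0.0 for v in rec["fraction_abs_error"].values())

    def test_truth_key_mismatch_is_an_error(self, simple_case):
        targets, dirs, mrna_de = simple_case
        table = classify_concordance(targets, dirs, mrna_de, TISSUE_MRNA)
        with pytest.raises(ValueError, match="absent from truth"):
            evaluate_recovery(table, {("hsa-miR-7", "A"): "IC"})
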