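"""FPKM, z-scaling, pattern grouping and efficiency-corrected qPCR ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from genefam import expression as expr
from genefam.synthetic_data import make_counts, make_ct


class TestFpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        lengths = pd.Series({"g1": 1000})
        totals = pd.Series({"s1": 1_000_000})
        assert expr.fpkm(counts, lengths, totals).loc["g1", "s1"] == 10.0

    def test_zero_counts_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0, 5]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 800})
        assert expr.fpkm(counts, lengths).loc["g1", "s1"] == 0.0

    def test_library_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [20, 60]},
                              index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 1500})
        out = expr.fpkm(counts, lengths)
        assert np.allclose(out["s1"], out["s2"])

    def test_length_scaling_exact(self):
        counts = pd.DataFrame({"s1": [10, 7]}, index=["g1", "g2"])
        base = expr.fpkm(counts, pd.Series({"g1": 1000, "g2": 400}))
        scaled = expr.fpkm(counts, pd.Series({"g1": 3000, "g2": 400}))
        assert scaled.loc["g1", "s1"] == pytest.approx(
            base.loc["g1", "s1"] / 3)

    def test_zero_library_is_error(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        with pytest.raises(ValueError, match="library"):
            expr.fpkm(counts, pd.Series({"g1": 100}))

    def test_silent_genes_dropped(self):
        mat = pd.DataFrame({"s1": [0.0, 1.0], "s2": [0.0, 2.0]},
                           index=["dead", "alive"])
        assert expr.drop_silent_genes(mat).index.tolist() == ["alive"]


class TestZscale:
    def test_simple_row(self):
        mat = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["g"])
        out = expr.zscale_rows(mat)
        assert out.loc["g"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_row_becomes_zeros_with_warning(self):
        mat = pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]}, index=["g"])
        with pytest.warns(UserWarning, match="constant"):
            out = expr.zscale_rows(mat)
        assert (out.loc["g"] == 0).all()

    def test_rows_standardized(self, rng):
        mat = pd.DataFrame(rng.uniform(0, 50, size=(10, 6)))
        out = expr.zscale_rows(mat)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)


class TestGrouping:
    def test_identical_rows_same_group(self):
        mat = pd.DataFrame([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0],
                            [5.0, 1.0, 0.0]],
                           index=["g1", "g2", "g3"])
        groups = expr.group_expression_patterns(expr.zscale_rows(mat), k=2)
        assert groups["g1"] == groups["g2"] != groups["g3"]

    def test_k1_single_group(self):
        mat = pd.DataFrame(np.arange(12, dtype=float).reshape(4, 3))
        groups = expr.group_expression_patterns(mat, k=1)
        assert set(groups.values()) == {1}

    def test_planted_temporal_patterns_recovered(self, rng):
        # early / mid / late peaks over a 0-4-12-24 h course
        profiles = {"early": [0, 5, 1, 0], "mid": [0, 1, 5, 1],
                    "late": [0, 0, 1, 5]}
        rows, labels = {}, {}
        for name, base in profiles.items():
            for i in range(4):
                g = f"{name}{i}"
                rows[g] = np.array(base, dtype=float) \
                    + rng.normal(0, 0.05, size=4)
                labels[g] = name
        mat = pd.DataFrame(rows).T
        mat.columns = ["0h", "4h", "12h", "24h"]
        groups = expr.group_expression_patterns(expr.zscale_rows(mat), k=3)
        for name in profiles:
            members = [g for g, l in labels.items() if l == name]
            assert len({groups[g] for g in members}) == 1


class TestDdct:
    def make_table(self, ct_map, e=2.0):
        rows = []
        for (gene, sample), ct in ct_map.items():
            role = "reference" if gene.startswith("ref") else "target"
            rows.append({"gene": gene, "sample": sample, "replicate": 1,
                         "ct": ct, "role": role, "efficiency": e})
        return pd.DataFrame(rows)

    def test_no_change_gives_unity(self):
        table = self.make_table({
            ("t", "c"): 20.0, ("t", "h"): 20.0,
            ("ref1", "c"): 18.0, ("ref1", "h"): 18.0,
            ("ref2", "c"): 22.0, ("ref2", "h"): 22.0})
        assert expr.ddct_ratio(table, "t", "h", "c") == pytest.approx(1.0)

    def test_two_cycles_earlier_is_fourfold(self):
        table = self.make_table({
            ("t", "c"): 22.0, ("t", "h"): 20.0,
            ("ref1", "c"): 18.0, ("ref1", "h"): 18.0,
            ("ref2", "c"): 22.0, ("ref2", "h"): 22.0})
        assert expr.ddct_ratio(table, "t", "h", "c") == pytest.approx(4.0)

    def test_control_vs_control_exactly_one(self):
        table = self.make_table({
            ("t", "c"): 21.3, ("ref1", "c"): 18.2, ("ref2", "c"): 24.9})
        assert expr.ddct_ratio(table, "t", "c", "c") == 1.0

    def test_reference_swap_symmetry(self):
        ct = {("t", "c"): 22.0, ("t", "h"): 19.0,
              ("ref1", "c"): 18.0, ("ref1", "h"): 17.2,
              ("ref2", "c"): 22.0, ("ref2", "h"): 23.1}
        table = self.make_table(ct)
        swapped = self.make_table({
            (g.replace("ref1", "tmp").replace("ref2", "ref1")
              .replace("tmp", "ref2"), s): v for (g, s), v in ct.items()})
        assert expr.ddct_ratio(table, "t", "h", "c") == pytest.approx(
            expr.ddct_ratio(swapped, "t", "h", "c"))

    def test_replicates_averaged(self):
        rows = []
        for rep, ct in enumerate([19.8, 20.2], 1):
            rows.append({"gene": "t", "sample": "h", "replicate": rep,
                         "ct": ct, "role": "target", "efficiency": 2.0})
        rows += self.make_table({
            ("t", "c"): 22.0,
            ("ref1", "c"): 18.0, ("ref1", "h"): 18.0,
            ("ref2", "c"): 22.0, ("ref2", "h"): 22.0}).to_dict("records")
        assert expr.ddct_ratio(pd.DataFrame(rows), "t", "h", "c") == \
            pytest.approx(4.0)

    def test_missing_reference_is_error(self):
        table = self.make_table({("t", "c"): 20.0, ("t", "h"): 19.0})
        with pytest.raises(ValueError, match="reference"):
            expr.ddct_ratio(table, "t", "h", "c")

    def test_bad_efficiency_rejected(self):
        table = self.make_table({
            ("t", "c"): 20.0, ("ref1", "c"): 18.0}, e=2.5)
        with pytest.raises(ValueError, match="efficienc"):
            expr.ddct_ratio(table, "t", "c", "c")


class TestSyntheticRecovery:
    def test_null_fold_changes_recover_unity(self):
        lfc = pd.DataFrame({"ctrl": 0.0, "heat": 0.0},
                           index=[f"g{i}" for i in range(200)])
        counts, lengths, truth = make_counts(
            {g: 1000 for g in lfc.index}, lfc, seed=3)
        fpkm = expr.fpkm(counts, lengths,
                         pd.Series(truth["library_size"],
                                   index=counts.columns))
        est = np.log2(fpkm["heat"] / fpkm["ctrl"])
        assert abs(float(np.median(est))) < 0.1

    def test_qpcr_fold_recovery_noise_free(self):
        table, _ = make_ct({"t": {"4h": 400.0}}, noise_sd=0.0, seed=0)
        # Ct values are stored to 4 decimals, hence the small tolerance
        assert expr.ddct_ratio(table, "t", "4h", "0h") == pytest.approx(
            400.0, rel=1e-3)


def test_replicate_anova_detects_separation():
    rows = []
    for sample, base in (("0h", 25.0), ("4h", 17.0)):
        for rep in range(1, 4):
            rows.append({"gene": "t", "sample": sample, "replicate": rep,
                         "ct": base + 0.05 * rep, "role": "target",
                         "efficiency": 2.0})
    f, p = expr.replicate_anova(pd.DataFrame(rows), "t")
    assert p < 0.01
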