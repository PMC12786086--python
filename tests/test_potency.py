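import numpy as np
import pandas as pd
import pytest

from scpotency.potency import (
    RestorationConfig,
    call_degs,
    classify_restored,
    deg_direction_counts,
    full_rescue_flags,
    group_means,
    intersect_disease_degs,
    report_fraction,
    restoration_score,
    transduction_profile,
    transgene_positive,
)
from tests.conftest import expression_from_array


def nb_counts(rng, mean, n, theta=2.0):
    return rng.poisson(rng.gamma(theta, mean / theta, size=n))


def cpm_from_counts(counts):
    """counts: genes x cells."""
    totals = counts.sum(axis=0)
    return counts / totals[None, :] * 1e6


class TestTransgenePositive:
    def test_single_count_is_positive(self):
        # 1 UMI in a 10,000-UMI cell -> 100 CPM, far above the 1e-4 gate
        e = expression_from_array([[100.0], [999900.0]], genes=["optiKCNV2", "G"],
                                  transgene_id="optiKCNV2")
        assert transgene_positive(e).tolist() == [True]

    def test_zero_count_negative(self):
        e = expression_from_array([[0.0], [1e6]], genes=["optiKCNV2", "G"],
                                  transgene_id="optiKCNV2")
        assert transgene_positive(e).tolist() == [False]

    def test_missing_transgene_rejected(self):
        e = expression_from_array([[1.0]])
        with pytest.raises(ValueError, match="transgene"):
            transgene_positive(e)

    def test_recovers_planted_rod_positivity(self, small_exp, small_results):
        cfg = small_exp.config
        tp = small_results.transduction
        row = tp[(tp["sample"] == "KO-RK") & (tp["cell_type"] == "Rods")]
        p = cfg.transduction_profile[("RK", "Rods")]
        n = int(row["n_cells"].iloc[0])
        assert abs(row["pct_positive"].iloc[0] / 100 - p) < 3 * np.sqrt(p * (1 - p) / n) + 0.03


class TestTransductionProfile:
    def test_simple_fraction(self):
        cells = pd.DataFrame(
            {"sample": ["s"] * 4, "cell_type": ["Rods"] * 4}
        )
        out = transduction_profile(cells, np.array([True, False, False, False]))
        row = out[out["cell_type"] == "Rods"]
        assert row["pct_positive"].iloc[0] == 25.0

    def test_absent_type_not_reported(self):
        cells = pd.DataFrame({"sample": ["s"] * 2, "cell_type": ["Rods", "Rods"]})
        out = transduction_profile(cells, np.array([False, False]))
        assert "Cones" not in out["cell_type"].tolist()

    def test_untreated_sample_is_all_negative(self, small_results):
        tp = small_results.transduction
        nt = tp[tp["sample"].isin(["CON-1", "KO-NT"])]
        assert (nt["pct_positive"] == 0).all()


class TestCallDegs:
    def make_dataset(self, seed=0, n_genes=60, n_per_side=300, folds=None):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(1.0, 0.6, size=n_genes)
        mean_a = base.copy()
        for idx, fold in (folds or {}).items():
            mean_a[idx] = base[idx] * fold if fold > 0 else base[idx] / -fold
        a = np.stack([nb_counts(rng, m, n_per_side) for m in mean_a])
        b = np.stack([nb_counts(rng, m, n_per_side) for m in base])
        counts = np.concatenate([a, b], axis=1).astype(float)
        counts[0, :] += 1  # keep library totals nonzero
        e = expression_from_array(cpm_from_counts(counts), scale="CPM")
        cells = pd.DataFrame(
            {
                "cell_type": ["Rods"] * (2 * n_per_side),
                "sample": ["D"] * n_per_side + ["C"] * n_per_side,
            }
        )
        disease = np.array([True] * n_per_side + [False] * n_per_side)
        return e, cells, disease, ~disease

    def test_planted_fold_detected_up(self):
        hits = 0
        for seed in range(5):
            e, cells, dis, con = self.make_dataset(seed=seed, folds={5: 1.5})
            degs = call_degs(e, cells, "Rods", dis, con)
            row = degs[degs["gene"] == "G5"]
            hits += bool(row["is_deg"].iloc[0] and row["direction"].iloc[0] == "up")
        assert hits >= 4  # power >= 0.9 at n=300/side, fold 1.5

    def test_small_fold_blocked_by_gate_regardless_of_p(self):
        # fold 1.1 with huge n: tiny p but below the 1.2 gate
        e, cells, dis, con = self.make_dataset(seed=3, n_per_side=800, folds={5: 1.1})
        degs = call_degs(e, cells, "Rods", dis, con)
        row = degs[degs["gene"] == "G5"].iloc[0]
        assert abs(row["signed_fc"]) < 1.2 and not row["is_deg"]

    def test_null_fdr_controlled(self):
        false_hits = []
        for seed in range(30):
            e, cells, dis, con = self.make_dataset(seed=100 + seed, n_genes=80, n_per_side=100)
            degs = call_degs(e, cells, "Rods", dis, con)
            false_hits.append(degs["is_deg"].any())
        # P(any BH discovery) under the global null <= alpha (+ MC slack)
        assert np.mean(false_hits) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 30)

    def test_min_cells_enforced(self):
        e, cells, dis, con = self.make_dataset(n_per_side=10)
        with pytest.raises(ValueError, match="need >="):
            call_degs(e, cells, "Rods", dis, con)


class TestIntersection:
    def deg_frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "cell_type", "direction", "is_deg"])

    def test_concordant_kept_discordant_dropped(self):
        ko = self.deg_frame([("A", "Rods", "up", True), ("B", "Rods", "up", True)])
        pt = self.deg_frame([("A", "Rods", "up", True), ("B", "Rods", "down", True)])
        out = intersect_disease_degs(ko, pt)
        assert out["gene"].tolist() == ["A"]

    def test_idempotent_on_identical_contrasts(self):
        ko = self.deg_frame(
            [("A", "Rods", "up", True), ("B", "Rods", "down", True), ("C", "Rods", "up", False)]
        )
        out = intersect_disease_degs(ko, ko)
        assert sorted(out["gene"]) == ["A", "B"]

    def test_matches_brute_force_set_logic(self):
        rng = np.random.default_rng(12)
        genes = [f"G{i}" for i in range(40)]
        mk = lambda: self.deg_frame(
            [
                (g, "Rods", rng.choice(["up", "down"]), bool(rng.random() < 0.5))
                for g in genes
            ]
        )
        ko, pt = mk(), mk()
        out = intersect_disease_degs(ko, pt)
        expected = set()
        for g in genes:
            k = ko[(ko.gene == g) & ko.is_deg]
            p = pt[(pt.gene == g) & pt.is_deg]
            if len(k) and len(p) and k["direction"].iloc[0] == p["direction"].iloc[0]:
                expected.add(g)
        assert set(out["gene"]) == expected

    def test_direction_counts(self):
        out = self.deg_frame(
            [("A", "Rods", "up", True), ("B", "Rods", "up", True), ("C", "Rods", "down", True)]
        )
        assert deg_direction_counts(out) == {"up": 2, "down": 1, "total": 3}


class TestRestorationScore:
    @pytest.mark.parametrize(
        "con,dis,trt,expected",
        [(10, 5, 6, 0.2), (10, 5, 10, 1.0), (10, 5, 5, 0.0), (10, 5, 4, -0.2), (5, 10, 9, 0.2)],
    )
    def test_examples(self, con, dis, trt, expected):
        imp, degenerate = restoration_score(con, dis, trt)
        assert imp == pytest.approx(expected) and not degenerate

    def test_degenerate_no_gap(self):
        imp, degenerate = restoration_score(5, 5, 7)
        assert imp == 0.0 and degenerate

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            restoration_score(-1, 2, 3)


def means_frame(rows):
    return pd.DataFrame(rows, columns=["control", "disease", "RK", "CAG"],
                        index=[f"G{i}" for i in range(len(rows))])


def dm_frame(n):
    return pd.DataFrame(
        {"gene": [f"G{i}" for i in range(n)], "cell_type": "Rods", "direction": "up"}
    )


class TestClassifyRestored:
    def test_mode_semantics(self):
        # improvements (0.25, 0.22) and (0.25, 0.10) via constructed means
        means = means_frame([(10, 5, 6.25, 6.1), (10, 5, 6.25, 5.5)])
        table_both, _ = classify_restored(dm_frame(2), means, RestorationConfig(mode="both"))
        table_any, _ = classify_restored(dm_frame(2), means, RestorationConfig(mode="any"))
        assert table_both["restored"].tolist() == [True, False]
        assert table_any["restored"].tolist() == [True, True]

    def test_exact_threshold_is_restored(self):
        means = means_frame([(10, 5, 6, 6)])  # improvement exactly 0.2 both vectors
        table, pct = classify_restored(dm_frame(1), means)
        assert table["restored"].iloc[0]
        assert pct == 100.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(13)
        rows = [(10.0, 5.0, 5 + 5 * rng.random(), 5 + 5 * rng.random()) for _ in range(30)]
        means = means_frame(rows)
        fracs = [
            classify_restored(dm_frame(30), means, RestorationConfig(threshold=t))[1]
            for t in (0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_overshoot_flagged_but_restored(self):
        means = means_frame([(10, 5, 11, 10)])  # RK improvement 1.2
        table, _ = classify_restored(dm_frame(1), means)
        assert table["restored"].iloc[0] and table["overshoot"].iloc[0]

    def test_worsening_not_restored(self):
        means = means_frame([(10, 5, 4, 4)])
        table, _ = classify_restored(dm_frame(1), means)
        assert not table["restored"].iloc[0]


class TestReportFraction:
    def test_published_style_arithmetic(self):
        assert report_fraction(32, 210) == pytest.approx(100 * 32 / 210)
        assert report_fraction(34, 152) == pytest.approx(100 * 34 / 152)

    def test_empty_set(self):
        assert np.isnan(report_fraction(0, 0))


class TestFullRescue:
    def build(self, seed, effect_fold=1.0, n_genes=150, n=120):
        # effect_fold applies to the first half of the genes (a global fold
        # would cancel under CPM normalisation)
        rng = np.random.default_rng(seed)
        base = rng.lognormal(1.0, 0.5, size=n_genes)
        mean_trt = base.copy()
        mean_trt[: n_genes // 2] *= effect_fold
        trt = np.stack([nb_counts(rng, m, n) for m in mean_trt]).astype(float)
        con = np.stack([nb_counts(rng, m, n) for m in base]).astype(float)
        counts = np.concatenate([trt, con], axis=1)
        counts[0] += 1
        e = expression_from_array(cpm_from_counts(counts), scale="CPM")
        cells = pd.DataFrame({"cell_type": ["Rods"] * 2 * n})
        treated = np.array([True] * n + [False] * n)
        dm = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(n_genes)], "cell_type": "Rods", "direction": "up"}
        )
        return dm, e, cells, treated

    def test_null_flags_true_about_one_minus_alpha(self):
        dm, e, cells, treated = self.build(seed=20)
        out = full_rescue_flags(dm, e, cells, "Rods", treated, ~treated)
        # treated == control in distribution: BH-adjusted p >= alpha nearly always
        assert out["full_rescue"].mean() > 0.9

    def test_large_effect_flagged_false(self):
        dm, e, cells, treated = self.build(seed=21, effect_fold=3.0)
        out = full_rescue_flags(dm, e, cells, "Rods", treated, ~treated)
        affected = out.iloc[: len(out) // 2]
        assert affected["full_rescue"].mean() < 0.1

    def test_empty_deg_set(self):
        dm, e, cells, treated = self.build(seed=22, n_genes=5)
        out = full_rescue_flags(dm.iloc[:0], e, cells, "Rods", treated, ~treated)
        assert len(out) == 0


def test_positives_only_improvements_exceed_diluted_estimates(small_exp):
    """Scoring on transgene-positive cells only undoes the dilution by
    partial transduction: improvement estimates should be at least the
    all-cell estimates for genuinely restored genes."""
    from scpotency import AnalysisConfig, PotencyAnalysis

    res_all = PotencyAnalysis.from_simulation(small_exp).fit()
    res_pos = PotencyAnalysis.from_simulation(
        small_exp, AnalysisConfig(restoration=RestorationConfig(positives_only=True))
    ).fit()
    truth_imp = small_exp.truth.improvements
    restored_genes = set(truth_imp.loc[truth_imp["improvement"] >= 0.4, "gene"])
    merged = res_all.restoration.merge(
        res_pos.restoration, on=["gene", "cell_type", "genotype"], suffixes=("_all", "_pos")
    )
    merged = merged[merged["gene"].isin(restored_genes)]
    assert len(merged) > 3
    for trt in ("RK", "CAG"):
        diff = merged[f"improvement_{trt}_pos"] - merged[f"improvement_{trt}_all"]
        assert diff.mean() > 0
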