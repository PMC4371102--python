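import math

import numpy as np
import pandas as pd
import pytest

from helpers import make_aggregates, make_wells
from mirqc import metrics
from mirqc.metrics import StandardDesign


class TestRecoverySummary:
    def _spikes(self, cqs, kit="Q"):
        return make_aggregates(
            [
                {"kit": kit, "assay_id": "cel-miR-39",
                 "sample_role": "spike_in", "sample_id": f"S{i:02d}",
                 "cq_avg": v}
                for i, v in enumerate(cqs)
            ]
        )

    def test_constant_group(self):
        out = metrics.recovery_summary(self._spikes([20.0, 20.0, 20.0]))
        row = out.iloc[0]
        assert row["median_cq"] == 20.0
        assert row["cv_pct"] == 0.0
        assert row["n"] == 3

    def test_hand_computed_cv(self):
        out = metrics.recovery_summary(self._spikes([20.0, 22.0]))
        row = out.iloc[0]
        assert row["median_cq"] == 21.0
        # sd = sqrt(2), mean = 21 -> CV = 100*sqrt(2)/21
        assert row["cv_pct"] == pytest.approx(100 * math.sqrt(2) / 21,
                                              abs=1e-9)

    def test_group_sizes_preserved_and_small_group_flagged(self):
        out = metrics.recovery_summary(
            pd.concat(
                [self._spikes(list(np.linspace(19, 21, 10))),
                 self._spikes([20.0], kit="NB")]
            )
        )
        by_kit = out.set_index("kit")
        assert by_kit.loc["Q", "n"] == 10
        assert by_kit.loc["NB", "cv_omitted"]
        assert math.isnan(by_kit.loc["NB", "cv_pct"])


class TestDdcq:
    @pytest.mark.parametrize(
        "calc, meas, expected",
        [(3.32, 3.32, 0.0), (3.32, 3.50, 0.18), (-2.0, -1.5, 0.5)],
    )
    def test_absolute_difference(self, calc, meas, expected):
        assert metrics.ddcq(calc, meas) == pytest.approx(expected)

    def test_symmetry_under_sign_convention(self):
        assert metrics.ddcq(3.32, 3.5) == metrics.ddcq(-3.32, -3.5)


def standard_agg(cqs_by_step, assay="miR-16"):
    return make_aggregates(
        [
            {"assay_id": assay, "sample_id": f"std_s{s}",
             "sample_role": "standard_point", "dilution_step": s,
             "cq_avg": v}
            for s, v in cqs_by_step.items()
        ]
    )


class TestAccuracyScores:
    design = StandardDesign(fold_per_step=10.0,
                            abundant_steps=(1, 2, 3, 4, 5),
                            low_steps=(6, 7))

    def _perfect(self):
        step = math.log2(10.0)
        return {s: 18.0 + (s - 1) * step for s in range(1, 8)}

    def test_perfect_series_scores_zero(self):
        a1, a2 = metrics.accuracy_scores(
            standard_agg(self._perfect()), self.design
        )
        assert a1 == pytest.approx(0.0, abs=1e-9)
        assert a2 == pytest.approx(0.0, abs=1e-9)

    def test_low_point_error_localises_to_a2(self):
        cqs = self._perfect()
        cqs[7] += 0.2
        a1, a2 = metrics.accuracy_scores(standard_agg(cqs), self.design)
        assert a1 == pytest.approx(0.0, abs=1e-9)
        assert a2 < -1e-3

    def test_two_fold_series_hand_enumerated(self):
        # steps 1..3 of a 2-fold series, measured Cq 20, 21.1, 22.0:
        # pairwise ddCq = {|1-1.1|, |2-2.0|, |1-0.9|} -> mean 0.0667
        design = StandardDesign(fold_per_step=2.0,
                                abundant_steps=(1, 2, 3), low_steps=())
        a1, _ = metrics.accuracy_scores(
            standard_agg({1: 20.0, 2: 21.1, 3: 22.0}), design
        )
        assert a1 == pytest.approx(-0.2 / 3, abs=1e-9)

    def test_slope_based_calculated_delta(self):
        """With a fitted slope supplied, the expected delta uses the
        observed efficiency instead of assuming one doubling/cycle."""
        design = StandardDesign(fold_per_step=10.0, slope=-3.5,
                                abundant_steps=(1, 2, 3), low_steps=())
        assert design.calculated_delta(1, 2) == pytest.approx(3.5)
        cqs = {s: 18.0 + (s - 1) * 3.5 for s in (1, 2, 3)}
        a1, _ = metrics.accuracy_scores(standard_agg(cqs), design)
        assert a1 == pytest.approx(0.0, abs=1e-9)

    def test_undetermined_point_pairs_skipped(self):
        cqs = self._perfect()
        cqs[6] = np.nan
        a1, a2 = metrics.accuracy_scores(standard_agg(cqs), self.design)
        assert a1 == pytest.approx(0.0, abs=1e-9)
        assert a2 == pytest.approx(0.0, abs=1e-9)  # only s7 pairs remain

    def test_scores_never_positive(self):
        rng = np.random.default_rng(4)
        cqs = {s: v + float(rng.normal(0, 0.3))
               for s, v in self._perfect().items()}
        a1, a2 = metrics.accuracy_scores(standard_agg(cqs), self.design)
        assert a1 <= 0 and a2 <= 0


class TestSensitivityScores:
    def _censored(self, plasma_cqs, titration_cqs):
        rows = [
            {"sample_id": f"S{i:02d}", "cq_avg": v}
            for i, v in enumerate(plasma_cqs)
        ] + [
            {"sample_id": f"tit_s{i}", "sample_role": "titration_point",
             "dilution_step": i + 1, "cq_avg": v}
            for i, v in enumerate(titration_cqs)
        ]
        df = make_aggregates(rows)
        df["cq_censored"] = df["cq_avg"].fillna(40.0)
        return df

    def test_proportions(self):
        cen = self._censored([30.0] * 8 + [40.0] * 2, [28.0, 40.0])
        s1, s2 = metrics.sensitivity_scores(cen)
        assert s1 == pytest.approx(0.8)
        assert s2 == pytest.approx(0.5)

    def test_all_censored_is_zero(self):
        s1, s2 = metrics.sensitivity_scores(
            self._censored([40.0] * 5, [40.0] * 3)
        )
        assert s1 == 0.0 and s2 == 0.0

    def test_empty_domain_undefined(self):
        cen = self._censored([30.0], [])
        _, s2 = metrics.sensitivity_scores(cen)
        assert math.isnan(s2)

    def test_invariant_to_relabeling(self):
        cen = self._censored([30.0] * 8 + [40.0] * 2, [28.0])
        shuffled = cen.sample(frac=1.0, random_state=0)
        shuffled["assay_id"] = "miR-99"
        assert metrics.sensitivity_scores(shuffled) == \
            metrics.sensitivity_scores(cen)


class TestReproducibilityScores:
    def _frames(self, rt2_offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = {f"S{i:02d}": float(rng.normal(30, 3)) for i in range(12)}
        rows, well_rows = [], []
        for rt in (1, 2):
            for s, v in base.items():
                val = v + (rt2_offset if rt == 2 else 0.0)
                rows.append({"sample_id": s, "rt_replicate": rt,
                             "cq_avg": val})
        for q in (1, 2):
            for s, v in base.items():
                well_rows.append({"sample_id": s, "qpcr_replicate": q,
                                  "cq": v})
        cen = make_aggregates(rows)
        cen["cq_censored"] = cen["cq_avg"]
        cen["censored"] = False
        norm = cen.copy()
        norm["norm_cq"] = norm["cq_censored"] - 20.0
        return cen, norm, make_wells(well_rows)

    def test_identical_replicates_score_one(self):
        cen, norm, wells = self._frames()
        r1, r2, r3 = metrics.reproducibility_scores(cen, norm, wells)
        assert r1 == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert r3 == pytest.approx(1.0, abs=1e-12)

    def test_systematic_rt_offset_lowers_absolute_agreement(self):
        cen, norm, wells = self._frames(rt2_offset=2.0)
        r1, _, r3 = metrics.reproducibility_scores(cen, norm, wells)
        assert r1 < 1.0
        assert r3 == pytest.approx(1.0, abs=1e-12)

    def test_analytic_variance_components_recovered(self):
        """Pairs with subject sd 3 and noise sd 1 have ICC 9/10."""
        from mirqc.stats import icc_twoway_mixed
        from mirqc.synthetic import simulate_two_rater

        x = simulate_two_rater(500, 3.0, 1.0, seed=21)
        res = icc_twoway_mixed(x, "absolute_agreement")
        assert res.icc == pytest.approx(0.9, abs=0.05)


class TestScoreTable:
    def test_two_systems_give_plus_minus_halfsqrt2(self):
        table = metrics.score_table(
            {
                "taqman": {"A1": -0.1, "S1": 0.9},
                "miscript": {"A1": -0.3, "S1": 0.7},
            }
        ).set_index("system")
        assert table.loc["taqman", "z_A1"] == pytest.approx(math.sqrt(0.5))
        assert table.loc["miscript", "z_A1"] == pytest.approx(-math.sqrt(0.5))

    def test_three_systems_standardised(self):
        table = metrics.score_table(
            {s: {"S1": v} for s, v in
             [("a", 0.5), ("b", 0.7), ("c", 0.95)]}
        )
        z = table["z_S1"].to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_tied_metric_flagged_undefined(self):
        table = metrics.score_table(
            {"a": {"S1": 0.8, "S2": 0.5}, "b": {"S1": 0.8, "S2": 0.6}}
        )
        assert table["z_S1"].isna().all()
        assert "S1" in table["z_undefined"].iloc[0]
        assert table["z_S2"].notna().all()
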