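"""Choice-table construction and mixed-model mate-choice tests."""

import numpy as np
import pytest

from mhcmate.inference import (
    ModelSpec,
    attach_taar_factor,
    build_choice_table,
    fit_choice_glmm,
    lrt_parametric_bootstrap,
    predicted_choice_curve,
    taar_interaction_test,
)
from mhcmate.randomization import observed_mean
from mhcmate.simulate import PreferenceSpec, simulate_choices
from mhcmate.types import ChoiceEvent, GenotypeTable


def _toy_events():
    gt = GenotypeTable({
        ("mom", "G"): {"a", "b"},
        ("m1", "G"): {"a", "c"},
        ("m2", "G"): {"c", "d"},
        ("m3", "G"): {"a", "b"},
    })
    ev = ChoiceEvent("o1", "mom", "m1", ("m1", "m2", "m3"), "C1", 2005)
    return gt, ev


class TestBuildChoiceTable:
    def test_one_row_per_candidate_one_chosen(self):
        gt, ev = _toy_events()
        table, log = build_choice_table([ev], gt, "G", "MALDis")
        assert len(table) == 3
        assert table["CHOSEN"].sum() == 1
        assert table.loc[table["CHOSEN"] == 1, "CANDIDATE"].item() == "m1"
        assert log["events_out"] == 1
        # MALDis hand values: m1 -> 1 (c), m2 -> 2 (c,d), m3 -> 0
        got = dict(zip(table["CANDIDATE"], table["MHC_INDEX"]))
        assert got == {"m1": 1.0, "m2": 2.0, "m3": 0.0}

    def test_event_with_only_father_genotyped_excluded(self):
        gt, ev = _toy_events()
        gt.drop("m2", "G")
        gt.drop("m3", "G")
        table, log = build_choice_table([ev], gt, "G", "MALDis")
        assert len(table) == 0 and log["too_few_candidates"] == 1

    def test_ungenotyped_mother_excluded_for_dissimilarity_only(self):
        gt, ev = _toy_events()
        gt.drop("mom", "G")
        t1, log1 = build_choice_table([ev], gt, "G", "MALDis")
        assert len(t1) == 0 and log1["no_mother_genotype"] == 1
        t2, log2 = build_choice_table([ev], gt, "G", "MALDiv")
        assert len(t2) == 3 and log2["events_out"] == 1

    def test_row_count_equals_total_pool_sizes(self, population, events_null, D1):
        events, _ = events_null
        gt = population.genotype_table()
        table, log = build_choice_table(events, gt, "MHC1", "MALDiv", D=D1)
        assert log["events_out"] == len(events)
        assert len(table) == sum(len(e.candidate_ids) for e in events)
        assert table["CHOSEN"].sum() == len(events)
        assert (table.groupby("OFFSPRING")["CHOSEN"].sum() == 1).all()

    def test_undefined_father_index_drops_event(self):
        # muAADis undefined for the father (identical genotypes)
        from mhcmate.indices import AADistanceMatrix

        gt = GenotypeTable({
            ("mom", "G"): {"a", "b"},
            ("m1", "G"): {"a", "b"},   # father, symdiff empty -> undefined
            ("m2", "G"): {"c", "d"},
        })
        D = AADistanceMatrix("G", ["a", "b", "c", "d"],
                             np.ones((4, 4), int) - np.eye(4, dtype=int))
        ev = ChoiceEvent("o1", "mom", "m1", ("m1", "m2"), "C1", 2005)
        table, log = build_choice_table([ev], gt, "G", "muAADis", D=D)
        assert len(table) == 0 and log["father_index_undefined"] == 1

    def test_observed_mean_matches_chosen_rows(self, population, events_null, D1):
        """Cross-module consistency: the randomization module's observed
        mean equals the mean index over CHOSEN=1 table rows."""
        events, _ = events_null
        gt = population.genotype_table()
        for index in ("MALDis", "MALDiv", "MAADiv"):
            table, _ = build_choice_table(events, gt, "MHC1", index, D=D1)
            om = observed_mean(events, gt, "MHC1", index, D=D1)
            assert om == pytest.approx(
                table.loc[table["CHOSEN"] == 1, "MHC_INDEX"].mean()
            )


class TestGlmmChoice:
    def test_null_table_slope_near_zero(self, population, events_null, D1):
        events, _ = events_null
        table, _ = build_choice_table(
            events, population.genotype_table(), "MHC1", "MALDiv", D=D1
        )
        fit = fit_choice_glmm(table)
        assert fit.converged
        assert abs(fit.slope) < 3 * fit.slope_se

    def test_standardize_reports_original_scale(self, population, events_null, D1):
        events, _ = events_null
        table, _ = build_choice_table(
            events, population.genotype_table(), "MHC1", "MALDiv", D=D1
        )
        raw = fit_choice_glmm(table)
        std = fit_choice_glmm(table, standardize=True)
        assert std.slope == pytest.approx(raw.slope, abs=0.02)

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            fit_choice_glmm(pd.DataFrame())


class TestLrt:
    def test_identical_specs_give_zero_statistic_p_one(
        self, population, events_null, D1
    ):
        events, _ = events_null
        table, _ = build_choice_table(
            events, population.genotype_table(), "MHC1", "MALDiv", D=D1
        )
        res = lrt_parametric_bootstrap(
            table, ModelSpec(index=True), ModelSpec(index=True), n_boot=19, seed=1
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == 1.0

    def test_extreme_statistic_gives_minimal_p(self, population, D1):
        events, _ = simulate_choices(
            population, PreferenceSpec("MALDiv", 2.0, "MHC1"), 200, 55, D=D1
        )
        table, _ = build_choice_table(
            events, population.genotype_table(), "MHC1", "MALDiv", D=D1
        )
        res = lrt_parametric_bootstrap(
            table, ModelSpec(index=True), ModelSpec(index=False), n_boot=19, seed=2
        )
        # observed statistic exceeds every null draw: minimal attainable p
        assert res.n_failed <= 1
        assert res.p_value == pytest.approx(1 / (res.n_boot + 1))

    def test_non_nested_specs_rejected(self, population, events_null, D1):
        events, _ = events_null
        table, _ = build_choice_table(
            events, population.genotype_table(), "MHC1", "MALDiv", D=D1
        )
        with pytest.raises(ValueError, match="nested"):
            lrt_parametric_bootstrap(
                table, ModelSpec(index=False), ModelSpec(index=True), n_boot=9, seed=1
            )

    def test_seeded_reproducibility(self, population, events_null, D1):
        events, _ = events_null
        table, _ = build_choice_table(
            events, population.genotype_table(), "MHC1", "MALDiv", D=D1
        )
        a = lrt_parametric_bootstrap(
            table, ModelSpec(index=True), ModelSpec(index=False), n_boot=29, seed=7
        )
        b = lrt_parametric_bootstrap(
            table, ModelSpec(index=True), ModelSpec(index=False), n_boot=29, seed=7
        )
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_statistics, b.null_statistics)


class TestPredictionCurve:
    def test_zero_slope_flat_positive_slope_increasing(
        self, population, events_null, D1
    ):
        events, _ = events_null
        table, _ = build_choice_table(
            events, population.genotype_table(), "MHC1", "MALDiv", D=D1
        )
        fit = fit_choice_glmm(table)
        grid = np.linspace(table["MHC_INDEX"].min(), table["MHC_INDEX"].max(), 9)
        fit.result.beta[:] = [-1.0, 0.0]
        curve = predicted_choice_curve(fit, grid, n_boot=5, seed=1)
        assert np.allclose(curve["prob"], curve["prob"].iloc[0])
        fit.result.beta[:] = [-1.0, 0.5]
        curve = predicted_choice_curve(fit, grid, n_boot=5, seed=1)
        assert (np.diff(curve["prob"]) > 0).all()
        assert not curve["extrapolated"].any()
        wide = predicted_choice_curve(fit, grid + 100, n_boot=5, seed=1)
        assert wide["extrapolated"].all()


class TestTaarFactor:
    def test_het_status_levels(self, population, events_null, D1):
        events, _ = events_null
        gt = population.genotype_table()
        table, _ = build_choice_table(events, gt, "MHC1", "MALDiv", D=D1)
        tab = attach_taar_factor(table, gt, "TAAR3", "het_status")
        assert set(tab["TAARlocus"]) <= {"het", "hom"}
        per_mother = tab.groupby("MOTHER")["TAARlocus"].nunique()
        assert (per_mother == 1).all()

    def test_allele_presence_mode(self, population, events_null, D1):
        events, _ = events_null
        gt = population.genotype_table()
        table, _ = build_choice_table(events, gt, "MHC1", "MALDiv", D=D1)
        tab = attach_taar_factor(
            table, gt, "TAAR3", "allele_presence", allele_id="TAAR3-01"
        )
        assert set(tab["TAARlocus"]) <= {"carrier", "noncarrier"}

    def test_constant_factor_rejected(self, population, events_null, D1):
        events, _ = events_null
        gt = population.genotype_table()
        table, _ = build_choice_table(events, gt, "MHC1", "MALDiv", D=D1)
        hom = GenotypeTable()
        for m in set(table["MOTHER"]):
            hom.set(m, "TAAR3", {"TAAR3-01"})
        with pytest.raises(ValueError, match="constant"):
            taar_interaction_test(table, hom, "TAAR3", n_boot=9, seed=1)

    def test_missing_mother_genotype_rejected(self, population, events_null, D1):
        events, _ = events_null
        gt = population.genotype_table()
        table, _ = build_choice_table(events, gt, "MHC1", "MALDiv", D=D1)
        gt2 = gt.copy()
        gt2.drop(table["MOTHER"].iloc[0], "TAAR3")
        with pytest.raises(ValueError, match="no TAAR3 genotype"):
            attach_taar_factor(table, gt2, "TAAR3")
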