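"""Lineage gating, quadrant fractions, positive fractions, top-decile RE."""

import numpy as np
import pandas as pd
import pytest

import mfiquant as mq
from mfiquant.calibration import ThresholdEntry, ThresholdSet
from mfiquant.phenotyping import (
    PhenotypingError,
    QuadrantFractions,
    T_LINEAGES,
    assign_lineages,
    call_phenotypes,
    call_quadrants,
    cohort_quadrant_fractions,
    conditional_coexpression,
    per_case_positive_fraction,
    top_decile_mean,
)
from mfiquant.synthetic import (
    CD3,
    CD4,
    CD8,
    CD20,
    FOXP3,
    PD1,
    TIGIT,
    generate_cell_table,
)

MARKERS = (CD20, CD3, CD4, CD8, FOXP3, TIGIT, PD1)


def _thresholds(cutoff=1.0):
    ts = ThresholdSet()
    for m in MARKERS:
        ts.set(ThresholdEntry(m, cutoff, 200, "x"))
    return ts


def _cells(rows):
    """rows: list of dicts of marker intensities (missing -> 0)."""
    recs = []
    for i, row in enumerate(rows):
        rec = {m: 0.0 for m in MARKERS}
        rec.update(row)
        rec["cell_id"] = i + 1
        rec["patient_id"] = row.get("patient_id", "P1")
        recs.append(rec)
    return pd.DataFrame(recs)


HI = 5.0  # above the unit test cutoff of 1.0


class TestAssignLineage:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ({CD20: HI}, "B_CELL"),
            ({CD20: HI, CD3: HI}, "B_CELL"),  # CD20 precedence
            ({CD3: HI, CD4: HI}, "T_CD4"),
            ({CD3: HI, CD8: HI}, "T_CD8"),
            ({CD3: HI, FOXP3: HI}, "T_FOXP3"),
            ({CD3: HI}, "T_OTHER"),
            ({CD3: HI, CD4: HI, FOXP3: HI}, "T_FOXP3"),  # rarest first
            ({CD3: HI, CD4: HI, CD8: HI}, "T_CD8"),
            ({}, "OTHER"),
            ({CD4: HI}, "OTHER"),  # subset marker without CD3
        ],
    )
    def test_gating_rules(self, row, expected):
        lineage = assign_lineages(_cells([row]), _thresholds())
        assert lineage.iloc[0] == expected

    def test_missing_lineage_channel_errors(self):
        cells = _cells([{CD3: HI}]).drop(columns=[FOXP3])
        with pytest.raises(PhenotypingError, match="FOXP3"):
            assign_lineages(cells, _thresholds())

    def test_missing_cutoff_errors(self):
        ts = _thresholds()
        del ts.entries[CD8]
        with pytest.raises(PhenotypingError, match="CD8"):
            assign_lineages(_cells([{CD3: HI}]), ts)

    def test_lineage_accuracy_on_separated_cohort(self):
        """Confusion vs generator truth on a well-separated cohort.

        With the order-statistic cutoff the false-positive rate per
        negative marker is ~1/(n_sample+1) regardless of separation, so
        the attainable accuracy depends on the population mix; this mix
        has a closed-form expectation of ~99.35%.
        """
        weights = {"B_CELL": 0.3, "T_CD4": 0.2, "T_CD8": 0.2, "T_FOXP3": 0.3}
        config = mq.nschl_quadrant_cohort(
            n_patients=1, n_cells=20000, seed=17, weights=weights
        )
        cells, truth = generate_cell_table(config)
        thresholds = mq.calibrate_thresholds(
            cells, truth["lineage"], seed=9
        )
        study = ~cells["is_reference"].to_numpy()
        called = assign_lineages(cells[study], thresholds)
        accuracy = (
            called.to_numpy() == truth.loc[study, "lineage"].to_numpy()
        ).mean()
        assert accuracy >= 0.99


class TestQuadrants:
    def test_printed_fraction_example(self):
        rows = (
            [{CD3: HI, TIGIT: HI, PD1: HI}] * 68
            + [{CD3: HI, TIGIT: HI}] * 14
            + [{CD3: HI, PD1: HI}] * 5
            + [{CD3: HI}] * 13
        )
        phenos = call_phenotypes(_cells(rows), _thresholds())
        qf = call_quadrants(phenos)
        assert qf.both == pytest.approx(0.68)
        assert qf.tigit_only == pytest.approx(0.14)
        assert qf.pd1_only == pytest.approx(0.05)
        assert qf.neither == pytest.approx(0.13)
        assert qf.n_cells == 100

    def test_all_double_negative(self):
        phenos = call_phenotypes(_cells([{CD3: HI}] * 7), _thresholds())
        qf = call_quadrants(phenos)
        assert (qf.both, qf.tigit_only, qf.pd1_only, qf.neither) == (
            0.0, 0.0, 0.0, 1.0,
        )

    def test_matches_brute_force_tally(self):
        """Fractions equal independent boolean counting exactly."""
        rng = np.random.default_rng(23)
        n = 10_000
        t = rng.random(n) < 0.6
        p = rng.random(n) < 0.5
        phenos = pd.DataFrame(
            {
                "patient_id": "P1",
                "lineage": "T_OTHER",
                "quadrant": np.where(
                    t & p, "both",
                    np.where(t, "tigit_only",
                             np.where(p, "pd1_only", "neither")),
                ),
            }
        )
        qf = call_quadrants(phenos)
        assert qf.both == (t & p).sum() / n
        assert qf.tigit_only == (t & ~p).sum() / n
        assert qf.pd1_only == (~t & p).sum() / n
        assert qf.neither == (~t & ~p).sum() / n

    def test_zero_t_cells_errors(self):
        phenos = call_phenotypes(_cells([{CD20: HI}]), _thresholds())
        with pytest.raises(PhenotypingError, match="CD3"):
            call_quadrants(phenos)

    def test_quadrant_consistent_with_positivity_bits(self, analyzed_cohort):
        _, result = analyzed_cohort
        t = result.phenotypes[result.phenotypes["lineage"].isin(T_LINEAGES)]
        expected = np.where(
            t["tigit_positive"] & t["pd1_positive"], "both",
            np.where(t["tigit_positive"], "tigit_only",
                     np.where(t["pd1_positive"], "pd1_only", "neither")),
        )
        assert (t["quadrant"].to_numpy() == expected).all()

    def test_cohort_mean_is_unweighted_over_patients(self):
        rows = (
            [{CD3: HI, TIGIT: HI, PD1: HI, "patient_id": "A"}] * 10
            + [{CD3: HI, "patient_id": "B"}] * 90
        )
        phenos = call_phenotypes(_cells(rows), _thresholds())
        mean_qf, pooled_qf, per_patient = cohort_quadrant_fractions(phenos)
        assert mean_qf.both == pytest.approx(0.5)  # (1.0 + 0.0)/2
        assert pooled_qf.both == pytest.approx(0.1)  # 10/100
        assert len(per_patient) == 2

    def test_parameter_recovery_on_synthetic_cohort(self, analyzed_cohort):
        """Recovered quadrants within 2 pp of the configured joint law."""
        config, result = analyzed_cohort
        target = config.patients[0].populations[1].quadrant_probs
        study = result.phenotypes[~result.cells["is_reference"].to_numpy()]
        mean_qf, _, _ = cohort_quadrant_fractions(study)
        for got, want in zip(
            (mean_qf.both, mean_qf.tigit_only, mean_qf.pd1_only,
             mean_qf.neither),
            target,
        ):
            assert abs(got - want) < 0.02


class TestPositiveFraction:
    def test_none_above_cutoff(self):
        cells = _cells([{TIGIT: 0.5}] * 10)
        assert per_case_positive_fraction(cells, TIGIT, _thresholds()) == 0.0

    def test_86_of_100(self):
        cells = _cells([{TIGIT: HI}] * 86 + [{TIGIT: 0.2}] * 14)
        assert per_case_positive_fraction(
            cells, TIGIT, _thresholds()
        ) == pytest.approx(0.86)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(31)
        vals = rng.lognormal(0, 1, 1000)
        cells = _cells([{TIGIT: v} for v in vals])
        ts = _thresholds(cutoff=1.0)
        frac = per_case_positive_fraction(cells, TIGIT, ts)
        assert frac == (vals > 1.0).sum() / 1000

    def test_raising_cutoff_never_increases_fraction(self):
        rng = np.random.default_rng(37)
        cells = _cells([{TIGIT: v} for v in rng.lognormal(0, 1, 500)])
        fracs = [
            per_case_positive_fraction(cells, TIGIT, _thresholds(c))
            for c in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestTopDecile:
    def test_single_top_element(self):
        s = top_decile_mean(np.arange(10.0, 101.0, 10.0), TIGIT, 0.1)
        assert s.mean_re == 100.0
        assert s.n_cells == 1

    def test_all_equal(self):
        s = top_decile_mean(np.full(50, 7.0), TIGIT, 0.1)
        assert s.mean_re == 7.0

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(41)
        vals = rng.lognormal(3, 1, 10_000)
        s = top_decile_mean(vals, TIGIT, 0.1)
        oracle = np.sort(vals)[::-1][:1000].mean()
        assert s.mean_re == pytest.approx(oracle, rel=0, abs=0)

    def test_top_decile_at_least_overall_mean(self):
        rng = np.random.default_rng(43)
        vals = rng.lognormal(0, 1, 5000)
        assert top_decile_mean(vals, TIGIT).mean_re >= vals.mean()

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(47)
        vals = rng.lognormal(0, 1, 5000)
        means = [
            top_decile_mean(vals, TIGIT, f).mean_re
            for f in (0.05, 0.1, 0.25, 0.5)
        ]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_tie_break_deterministic_by_cell_id(self):
        vals = [5.0, 5.0, 5.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        ids = np.arange(10)
        a = top_decile_mean(vals, TIGIT, 0.1, cell_ids=ids)
        b = top_decile_mean(vals, TIGIT, 0.1, cell_ids=ids)
        assert a.mean_re == b.mean_re == 5.0

    def test_empty_errors(self):
        with pytest.raises(PhenotypingError):
            top_decile_mean([], TIGIT)

    def test_bad_fraction_errors(self):
        with pytest.raises(PhenotypingError, match="fraction"):
            top_decile_mean([1.0] * 20, TIGIT, fraction=1.5)


class TestConditionalCoexpression:
    def test_printed_fractions_give_83_percent(self):
        qf = QuadrantFractions(0.68, 0.14, 0.05, 0.13, n_cells=100)
        out = conditional_coexpression(qf)
        assert out["pd1_given_tigit"] == pytest.approx(0.68 / 0.82)
        assert out["pd1_given_tigit"] > 0.80

    def test_no_single_positives(self):
        qf = QuadrantFractions(0.6, 0.0, 0.0, 0.4, n_cells=10)
        out = conditional_coexpression(qf)
        assert out["pd1_given_tigit"] == 1.0
        assert out["tigit_given_pd1"] == 1.0

    def test_zero_denominator_undefined(self):
        qf = QuadrantFractions(0.0, 0.0, 0.3, 0.7, n_cells=10)
        assert conditional_coexpression(qf)["pd1_given_tigit"] is None

    def test_agrees_with_cell_level_counting(self):
        rng = np.random.default_rng(53)
        n = 20_000
        t = rng.random(n) < 0.7
        p = np.where(t, rng.random(n) < 0.85, rng.random(n) < 0.3)
        quadrant = np.where(
            t & (p == 1), "both",
            np.where(t, "tigit_only", np.where(p == 1, "pd1_only", "neither")),
        )
        phenos = pd.DataFrame(
            {"patient_id": "P1", "lineage": "T_OTHER", "quadrant": quadrant}
        )
        out = conditional_coexpression(call_quadrants(phenos))
        direct = (t & (p == 1)).sum() / t.sum()
        assert out["pd1_given_tigit"] == pytest.approx(direct)
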