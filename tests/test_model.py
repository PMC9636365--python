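"""Unit and property tests for baselines, cut-offs, scoring, classification,
respiration referencing, the score-respiration correlation and pooled stats."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import overreach as ov
from overreach.model import pooled_mean

from conftest import brute_force_scores


def make_panels(values_by_subject_phase):
    rows = []
    for (subj, phase), vals in values_by_subject_phase.items():
        rows.append({"subject_id": subj, "phase_id": phase, **vals})
    df = pd.DataFrame(rows)
    for p in ov.DEFAULT_PARAMETERS:
        if p.name not in df:
            df[p.name] = 10.0
    return df


class TestBaselines:
    def test_mean_over_normal_phases(self):
        panels = make_panels(
            {("A", ph): {"poms_fatigue": v} for ph, v in zip(["BL", "LT", "MT1", "RE"], [40, 42, 44, 46])}
        )
        b = ov.compute_baselines(panels)
        assert b.values.loc["A", "poms_fatigue"] == 43.0
        assert b.counts.loc["A", "poms_fatigue"] == 4

    def test_constant_input_and_bounds(self):
        panels = make_panels(
            {("A", ph): {"poms_fatigue": 37.5} for ph in ["BL", "LT", "MT1", "RE"]}
        )
        b = ov.compute_baselines(panels)
        assert b.values.loc["A", "poms_fatigue"] == 37.5

    def test_missing_phase_reduces_count_with_warning(self):
        panels = make_panels(
            {("A", ph): {"poms_fatigue": v} for ph, v in zip(["BL", "LT", "MT1"], [40, 42, 44])}
        )
        with pytest.warns(UserWarning, match="3/4 normal phases"):
            b = ov.compute_baselines(panels)
        assert b.values.loc["A", "poms_fatigue"] == 42.0
        assert b.counts.loc["A", "poms_fatigue"] == 3

    def test_no_usable_value_is_hard_error(self):
        panels = make_panels({("A", "BL"): {"poms_fatigue": np.nan}})
        panels.loc[:, "poms_fatigue"] = np.nan
        with pytest.raises(ValueError, match="poms_fatigue"):
            ov.compute_baselines(panels)

    def test_baseline_within_contributing_range(self):
        rng = np.random.default_rng(7)
        panels = make_panels(
            {("A", ph): {"poms_fatigue": rng.uniform(30, 60)} for ph in ["BL", "LT", "MT1", "RE"]}
        )
        b = ov.compute_baselines(panels)
        vals = panels["poms_fatigue"]
        assert vals.min() <= b.values.loc["A", "poms_fatigue"] <= vals.max()


class TestCutoffs:
    def test_printed_group_means_reproduce_mean_diffs(self):
        """Half-of-group-mean-difference arithmetic on the published group means."""
        cut = ov.reference_cutoffs()
        diffs = (cut.mal_means - cut.normal_means).round(2)
        assert diffs.to_dict() == {
            "poms_fatigue": 9.3,
            "hr_max": -5.1,
            "glucose_end": -1.43,
            "lactate_end": -1.25,
            "rpe_mean": 1.0,
        }
        assert cut.values["rpe_mean"] == pytest.approx(0.5)
        # full precision retained: 4.65, not the display-rounded 4.7
        assert cut.values["poms_fatigue"] == pytest.approx(4.65)

    def test_derived_from_cohort(self, tiny_cohort):
        cut = ov.derive_cutoffs(tiny_cohort)
        # MAL shifts are identical for both subjects, so cut-off = shift / 2
        assert cut.values["poms_fatigue"] == pytest.approx(5.0)
        assert cut.values["hr_max"] == pytest.approx(-3.0)
        assert cut.provenance == "derived"

    def test_zero_difference_warns_direction_mismatch(self, tiny_cohort):
        flat = tiny_cohort.copy()
        flat["rpe_mean"] = 17.0
        with pytest.warns(UserWarning, match="rpe_mean"):
            cut = ov.derive_cutoffs(flat)
        assert cut.values["rpe_mean"] == 0.0

    def test_pooling_modes_differ_with_unbalanced_data(self, tiny_cohort):
        unbalanced = tiny_cohort[
            ~((tiny_cohort.subject_id == "B") & tiny_cohort.phase_id.isin(["BL", "LT"]))
        ]
        obs = ov.derive_cutoffs(unbalanced, pooling="observations")
        subj = ov.derive_cutoffs(unbalanced, pooling="subjects")
        assert obs.values["poms_fatigue"] != pytest.approx(subj.values["poms_fatigue"])

    def test_requires_mal_phase(self, tiny_cohort):
        with pytest.raises(ValueError, match="MAL"):
            ov.derive_cutoffs(tiny_cohort[tiny_cohort.phase_id != "MAL"])

    def test_individual_cutoffs_per_subject(self, tiny_cohort):
        cut = ov.individual_cutoffs(tiny_cohort)
        assert cut.per_subject
        # subject A: MAL poms 50, baseline 40 -> cut-off +5
        assert cut.values.loc["A", "poms_fatigue"] == pytest.approx(5.0)


class TestScoring:
    def test_adverse_deviation_beyond_cutoff_scores_one(self):
        panels = make_panels(
            {("A", ph): {"hr_max": 185.0} for ph in ["BL", "LT", "MT1", "RE"]}
            | {("A", "MAL"): {"hr_max": 182.0}}
        )
        b = ov.compute_baselines(panels)
        cut = ov.fixed_cutoffs({p.name: v for p, v in zip(ov.DEFAULT_PARAMETERS, [4.7, -2.5, -0.71, -0.62, 0.5])})
        sm = ov.score(panels, b, cut)
        assert sm.scores.loc[("A", "MAL"), "hr_max"] == 1

    def test_boundary_deviation_scores_zero(self):
        """Deviation exactly equal to the cut-off does not score (strict rule).

        Values chosen exactly representable in binary so the tie is exact."""
        panels = make_panels(
            {("A", ph): {"rpe_mean": 17.0} for ph in ["BL", "LT", "MT1", "RE"]}
            | {("A", "MAL"): {"rpe_mean": 17.5}}
        )
        b = ov.compute_baselines(panels)
        cut = ov.fixed_cutoffs({"poms_fatigue": 4.7, "hr_max": -2.5, "glucose_end": -0.71, "lactate_end": -0.62, "rpe_mean": 0.5})
        sm = ov.score(panels, b, cut)
        assert sm.scores.loc[("A", "MAL"), "rpe_mean"] == 0
        # one step beyond the tie does score
        panels.loc[panels.phase_id == "MAL", "rpe_mean"] = 17.75
        sm = ov.score(panels, ov.compute_baselines(panels), cut)
        assert sm.scores.loc[("A", "MAL"), "rpe_mean"] == 1

    def test_zero_deviation_row_all_zero(self, tiny_cohort):
        b = ov.compute_baselines(tiny_cohort)
        cut = ov.derive_cutoffs(tiny_cohort)
        sm = ov.score(tiny_cohort, b, cut)
        # observed == baseline in MT2 (constant across normal phases and MT2)
        assert sm.scores.loc[("A", "MT2")].sum() == 0

    def test_missing_observation_scores_zero_and_flagged(self, tiny_cohort):
        holey = tiny_cohort.copy()
        holey.loc[(holey.subject_id == "A") & (holey.phase_id == "MAL"), "hr_max"] = np.nan
        b = ov.compute_baselines(holey)
        cut = ov.fixed_cutoffs(dict(ov.PUBLISHED_CUTOFFS))
        sm = ov.score(holey, b, cut)
        assert sm.scores.loc[("A", "MAL"), "hr_max"] == 0
        assert bool(sm.missing.loc[("A", "MAL"), "hr_max"])

    def test_translation_invariance(self, tiny_cohort):
        """Adding a constant to one subject's observations shifts the baseline
        equally and leaves every score unchanged."""
        cut = ov.fixed_cutoffs(dict(ov.PUBLISHED_CUTOFFS))
        sm1 = ov.score(tiny_cohort, ov.compute_baselines(tiny_cohort), cut)
        shifted = tiny_cohort.copy()
        mask = shifted.subject_id == "A"
        shifted.loc[mask, "poms_fatigue"] += 123.4
        sm2 = ov.score(shifted, ov.compute_baselines(shifted), cut)
        pd.testing.assert_frame_equal(sm1.scores, sm2.scores)

    def test_monotone_in_adverse_deviation(self, tiny_cohort):
        """Pushing an observation further in the adverse direction never turns
        a 1 into a 0."""
        cut = ov.fixed_cutoffs(dict(ov.PUBLISHED_CUTOFFS))
        sm1 = ov.score(tiny_cohort, ov.compute_baselines(tiny_cohort), cut)
        worse = tiny_cohort.copy()
        mal = worse.phase_id == "MAL"
        worse.loc[mal, "poms_fatigue"] += 5.0  # adverse direction +1
        worse.loc[mal, "hr_max"] -= 5.0  # adverse direction -1
        # baselines from the *original* panel: pure deviation increase
        sm2 = ov.score(worse, ov.compute_baselines(tiny_cohort), cut)
        assert (sm2.scores >= sm1.scores).all().all()

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        """Vectorised scoring equals a plain-loop evaluation of the inequality
        on random cohorts of up to 12 subjects."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        rows = []
        for i in range(n):
            for ph in ("BL", "LT", "MT1", "MT2", "MAL", "RE"):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "phase_id": ph,
                        **{
                            p.name: rng.normal(50, 10) if rng.random() > 0.05 else np.nan
                            for p in ov.DEFAULT_PARAMETERS
                        },
                    }
                )
        panels = pd.DataFrame(rows)
        for p in ov.DEFAULT_PARAMETERS:  # keep baselines and group means defined
            for ph in ("BL", "MAL"):
                panels.loc[panels.phase_id == ph, p.name] = panels.loc[
                    panels.phase_id == ph, p.name
                ].fillna(50.0)
        b = ov.compute_baselines(panels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cut = ov.derive_cutoffs(panels)
        sm = ov.score(panels, b, cut)
        expected = brute_force_scores(panels, b, cut)
        pd.testing.assert_frame_equal(
            sm.scores, expected[sm.scores.columns], check_dtype=False
        )


class TestClassify:
    def test_reference_fixture_flags_all_eleven_at_mal(self, reference_matrix):
        cls = ov.classify(reference_matrix, threshold=3)
        mal = cls[(cls.phase_id == "MAL") & cls.flagged]
        assert len(mal) == 11

    def test_all_zero_matrix_flags_nobody(self):
        idx = pd.MultiIndex.from_product(
            [["A", "B"], ["BL", "MAL"]], names=["subject_id", "phase_id"]
        )
        sm = ov.ScoreMatrix(scores=pd.DataFrame(0, index=idx, columns=list(ov.PUBLISHED_CUTOFFS)))
        assert not ov.classify(sm).flagged.any()

    def test_threshold_boundary(self):
        idx = pd.MultiIndex.from_tuples([("A", "MAL")], names=["subject_id", "phase_id"])
        sm = ov.ScoreMatrix(
            scores=pd.DataFrame([[1, 1, 1, 0, 0]], index=idx, columns=list(ov.PUBLISHED_CUTOFFS))
        )
        assert ov.classify(sm, threshold=3).flagged.iloc[0]
        assert not ov.classify(sm, threshold=4).flagged.iloc[0]

    def test_monotone_in_threshold(self, reference_matrix):
        flagged = {
            t: set(
                map(
                    tuple,
                    ov.classify(reference_matrix, t)
                    .query("flagged")[["subject_id", "phase_id"]]
                    .itertuples(index=False),
                )
            )
            for t in range(1, 6)
        }
        for t in range(1, 5):
            assert flagged[t + 1] <= flagged[t]

    def test_invalid_threshold(self, reference_matrix):
        with pytest.raises(ValueError):
            ov.classify(reference_matrix, threshold=0)


class TestRespiration:
    def make_records(self, per_phase):
        return pd.DataFrame(
            [
                {"subject_id": "A", "phase_id": ph, "respiration": v}
                for ph, v in per_phase.items()
            ]
        )

    def test_normal_mean_and_mal_delta(self):
        rec = self.make_records({"BL": 10, "LT": 10, "MT1": 10, "RE": 10, "MAL": 6})
        out = ov.respiration_deltas(rec)
        assert (out.normal_respiration == 10).all()
        assert out.loc[out.phase_id == "MAL", "delta"].iloc[0] == -4

    def test_normal_deltas_sum_to_zero(self):
        rec = self.make_records({"BL": 8, "LT": 10, "MT1": 12, "RE": 10, "MAL": 5})
        out = ov.respiration_deltas(rec)
        normal = out[out.phase_id.isin(["BL", "LT", "MT1", "RE"])]
        assert normal.delta.sum() == pytest.approx(0.0, abs=1e-12)
        assert list(normal.delta) == pytest.approx([-2, 0, 2, 0])

    def test_all_equal_gives_zero_deltas(self):
        rec = self.make_records({"BL": 7, "LT": 7, "MT1": 7, "RE": 7, "MAL": 7})
        assert (ov.respiration_deltas(rec).delta == 0).all()

    def test_missing_normal_phase_warns(self):
        rec = self.make_records({"BL": 8, "LT": 10, "MT1": 12, "MAL": 5})
        with pytest.warns(UserWarning, match="3/4"):
            out = ov.respiration_deltas(rec)
        assert (out.normal_respiration == 10).all()

    def test_no_normal_phase_errors(self):
        rec = self.make_records({"MAL": 5})
        with pytest.raises(ValueError, match="no normal-phase respiration"):
            ov.respiration_deltas(rec)


class TestCorrelation:
    def pairs_frame(self, pairs, phase="MAL"):
        scores = pd.Series(
            [p[0] for p in pairs],
            index=pd.MultiIndex.from_tuples(
                [(f"S{i}", phase) for i in range(len(pairs))],
                names=["subject_id", "phase_id"],
            ),
            name="n_scores",
        )
        deltas = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(pairs))],
                "phase_id": phase,
                "delta": [p[1] for p in pairs],
            }
        )
        return scores, deltas

    def test_perfect_negative_linear(self):
        s, d = self.pairs_frame([(0, 0), (1, -1), (2, -2), (3, -3)])
        rep = ov.correlate_scores_respiration(s, d)
        assert rep.r == pytest.approx(-1.0)
        assert rep.n == 4

    def test_hand_computed_r(self):
        # sum dxdy=-13.5, sum dx^2=14.75, sum dy^2=13 -> r=-13.5/sqrt(191.75)
        s, d = self.pairs_frame([(0, 1), (1, -1), (3, -2), (5, -4)])
        rep = ov.correlate_scores_respiration(s, d)
        assert rep.r == pytest.approx(-0.9749, abs=1e-4)
        assert 0 < rep.p < 1

    def test_zero_variance_errors(self):
        s, d = self.pairs_frame([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError, match="zero variance"):
            ov.correlate_scores_respiration(s, d)

    def test_excludes_phases_without_biopsy(self):
        s, d = self.pairs_frame([(0, 0), (1, -1), (2, -2), (3, -3)])
        extra_s, extra_d = self.pairs_frame([(5, 9)], phase="MT2")
        s = pd.concat([s, extra_s])
        d = pd.concat([d, extra_d], ignore_index=True)
        rep = ov.correlate_scores_respiration(s, d)
        assert rep.n == 4 and rep.r == pytest.approx(-1.0)


class TestPooledStats:
    @pytest.mark.parametrize(
        "strata,expected",
        [
            ([(6, 2848), (5, 3947)], 3348),  # maximal oxygen uptake (mL/min)
            ([(6, 233), (5, 303)], 265),  # maximal aerobic power (W)
            ([(6, 156), (5, 202)], 177),  # lactate threshold (W)
            ([(6, 165), (5, 179)], 171),  # height (cm)
            ([(6, 61), (5, 78)], 69),  # body mass (kg)
        ],
    )
    def test_sex_stratified_pooling_matches_printed_all_row(self, strata, expected):
        assert pooled_mean(strata) == expected

    def test_single_stratum_is_identity(self):
        assert pooled_mean([(7, 42.5)]) == 42.5

    def test_zero_total_n_errors(self):
        with pytest.raises(ValueError):
            pooled_mean([])
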