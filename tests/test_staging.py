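"""Two-step staging automaton: severity coding, stage rules, invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pspstage import regions as R
from pspstage.staging import (
    STEP2_NUMERIC,
    aggregate_composite,
    assign_stage_step1,
    assign_substage,
    severity_score,
    stage_cohort,
    stage_from_severity,
)
from pspstage.thresholds import FALLBACK_W, ThresholdEntry, sd_threshold


def fallback_thresholds():
    return {sub: ThresholdEntry(region=sub, tau=FALLBACK_W, source="fallback") for sub in R.SUBREGIONS}


class TestSeverityScore:
    @pytest.mark.parametrize(
        "w,tau,expected",
        [
            (0.795, 0.795, 0),  # at threshold: absent
            (0.9, 0.795, 1),  # above threshold: mild/moderate
            (1.60, 0.795, 2),  # above 2*tau = 1.59: moderate/severe
            (1.59, 0.795, 1),  # exactly 2*tau: still mild (strict >)
            (2.0, 1.0, 1),
            (-3.0, 1.0, 0),
        ],
    )
    def test_three_level_rule(self, w, tau, expected):
        assert severity_score(w, tau) == expected

    def test_guards(self):
        with pytest.raises(ValueError):
            severity_score(1.0, 0.0)
        with pytest.raises(ValueError):
            severity_score(float("nan"), 1.0)


class TestCompositeAggregation:
    @pytest.mark.parametrize("sevs,expected", [([1, 0], 1), ([2, 1], 2), ([0, 0], 0), ([2], 2)])
    def test_max_rule(self, sevs, expected):
        assert aggregate_composite(sevs) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_composite([])


class TestStep1:
    @pytest.mark.parametrize(
        "presence,expected,atypical",
        [
            ({"GP": 0, "CER": 0, "FR": 0, "OCC": 0}, "no_stage", False),
            ({"GP": 1, "CER": 0, "FR": 0, "OCC": 0}, "I/II", False),
            ({"GP": 1, "CER": 1, "FR": 0, "OCC": 0}, "III/IV", False),
            ({"GP": 1, "CER": 0, "FR": 1, "OCC": 0}, "III/IV", False),
            ({"GP": 1, "CER": 1, "FR": 0, "OCC": 1}, "V/VI", False),
            ({"GP": 1, "CER": 0, "FR": 0, "OCC": 1}, "V/VI", True),  # atypical
            ({"GP": 0, "CER": 0, "FR": 1, "OCC": 0}, "unclassifiable", False),
            ({"GP": 0, "CER": 1, "FR": 1, "OCC": 1}, "unclassifiable", False),
        ],
    )
    def test_cumulative_rules(self, presence, expected, atypical):
        step1, flag = assign_stage_step1(presence)
        assert step1 == expected
        assert flag is atypical

    def test_missing_composite_rejected(self):
        with pytest.raises(ValueError, match="OCC"):
            assign_stage_step1({"GP": 1, "CER": 0, "FR": 0})


class TestSubstage:
    @pytest.mark.parametrize(
        "step1,severity,expected",
        [
            ("I/II", {"GP": 1, "CER": 0, "FR": 0, "OCC": 0}, "I"),
            ("I/II", {"GP": 2, "CER": 0, "FR": 0, "OCC": 0}, "II"),
            ("III/IV", {"GP": 2, "CER": 1, "FR": 0, "OCC": 0}, "III"),
            ("III/IV", {"GP": 1, "CER": 2, "FR": 1, "OCC": 0}, "IV"),
            ("V/VI", {"GP": 2, "CER": 2, "FR": 2, "OCC": 1}, "V"),
            ("V/VI", {"GP": 2, "CER": 2, "FR": 2, "OCC": 2}, "VI"),
            ("no_stage", {"GP": 0, "CER": 0, "FR": 0, "OCC": 0}, "no_stage"),
        ],
    )
    def test_severity_refinement(self, step1, severity, expected):
        assert assign_substage(step1, severity) == expected

    def test_inconsistent_severity_rejected(self):
        with pytest.raises(ValueError):
            assign_substage("I/II", {"GP": 0, "CER": 0, "FR": 0, "OCC": 0})


class TestAutomatonInvariants:
    ALL_VECTORS = list(itertools.product((0, 1, 2), repeat=4))

    def assignments(self):
        out = {}
        for vec in self.ALL_VECTORS:
            sev = dict(zip(("GP", "CER", "FR", "OCC"), vec))
            out[vec] = stage_from_severity(sev)
        return out

    def test_exhaustive_and_single_valued(self):
        """Every one of the 81 severity vectors maps to exactly one step-2
        outcome without error."""
        outcomes = self.assignments()
        assert len(outcomes) == 81
        valid = set(STEP2_NUMERIC) | {"unclassifiable"}
        assert all(a.step2 in valid for a in outcomes.values())

    def test_step2_refines_step1(self):
        pairs = {"I": "I/II", "II": "I/II", "III": "III/IV", "IV": "III/IV",
                 "V": "V/VI", "VI": "V/VI", "no_stage": "no_stage",
                 "unclassifiable": "unclassifiable"}
        for a in self.assignments().values():
            assert pairs[a.step2] == a.step1

    def test_monotone_in_each_severity(self):
        """Raising any single composite severity never lowers the numeric
        stage (unclassifiable excluded from the order)."""
        outcomes = self.assignments()
        for vec, a in outcomes.items():
            if not np.isfinite(a.numeric_stage):
                continue
            for i in range(4):
                if vec[i] < 2:
                    up = list(vec)
                    up[i] += 1
                    b = outcomes[tuple(up)]
                    if np.isfinite(b.numeric_stage):
                        assert b.numeric_stage >= a.numeric_stage, (vec, up)

    def test_unclassifiable_iff_sequence_violated(self):
        for vec, a in self.assignments().items():
            gp, others = vec[0], vec[1:]
            expected = gp == 0 and any(s > 0 for s in others)
            assert (a.step1 == "unclassifiable") == expected


class TestStageCohort:
    def wtable(self, rows):
        recs = []
        for i, wvals in enumerate(rows):
            rec = {"subject_id": f"s{i}", "group": "patient"}
            rec.update({R.wscore_col(sub): wvals.get(sub, 0.0) for sub in R.SUBREGIONS})
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_all_below_threshold_is_no_stage(self):
        staged = stage_cohort(self.wtable([{}, {}]), fallback_thresholds())
        assert (staged["step2"] == "no_stage").all()

    def test_gp_only_cohort_all_stage_I(self):
        rows = [{"gp": FALLBACK_W + 0.1} for _ in range(5)]
        staged = stage_cohort(self.wtable(rows), fallback_thresholds())
        assert (staged["step2"] == "I").all()

    def test_threshold_monotonicity(self):
        """Raising any region's threshold never increases any stage."""
        rng = np.random.default_rng(21)
        rows = [
            {sub: rng.normal(1.5, 1.5) for sub in R.SUBREGIONS} for _ in range(60)
        ]
        base = {sub: sd_threshold(sub, 1.0) for sub in R.SUBREGIONS}
        staged0 = stage_cohort(self.wtable(rows), base)
        for raise_sub in R.SUBREGIONS:
            higher = dict(base)
            higher[raise_sub] = sd_threshold(raise_sub, 1.8)
            staged1 = stage_cohort(self.wtable(rows), higher)
            m = staged0["numeric_stage"].notna() & staged1["numeric_stage"].notna()
            assert (staged1.loc[m, "numeric_stage"] <= staged0.loc[m, "numeric_stage"]).all()

    def test_missing_region_staged_only_when_outcome_forced(self):
        # missing CER cannot change the outcome: FR already severe
        forced = self.wtable([{"gp": 2.0, "fr": 4.0}])
        forced.loc[0, R.wscore_col("cer_wm")] = np.nan
        forced.loc[0, R.wscore_col("cer_dn")] = np.nan
        staged = stage_cohort(forced, fallback_thresholds())
        assert staged.loc[0, "step2"] == "IV"
        # missing GP decides between no_stage and unclassifiable
        open_case = self.wtable([{"fr": 0.0}])
        open_case.loc[0, R.wscore_col("gp")] = np.nan
        staged2 = stage_cohort(open_case, fallback_thresholds())
        assert staged2.loc[0, "step2"] == "unclassifiable_missing"
        assert np.isnan(staged2.loc[0, "numeric_stage"])

    def test_missing_threshold_rejected(self):
        ts = fallback_thresholds()
        del ts["gp"]
        with pytest.raises(ValueError, match="gp"):
            stage_cohort(self.wtable([{}]), ts)

    def test_occ_combined_mode(self):
        """Combined-occipital mode thresholds the mean of the two occipital
        w-scores; a subject mildly positive in one subregion only can drop
        below the combined cut."""
        rows = [{"gp": 2.5, "fr": 2.5, "occ_ling": 1.8, "occ_cun": 0.0}]
        per_sub = stage_cohort(self.wtable(rows), fallback_thresholds())
        combined = stage_cohort(self.wtable(rows), fallback_thresholds(), occ_combined=True)
        assert per_sub.loc[0, "step2"] == "V"
        assert combined.loc[0, "step2"] == "III"

    def test_recovers_true_stages_with_strong_signal(self):
        """Generator truth is recovered for nearly all patients under large
        effects and small noise (SD-rule thresholds)."""
        from pspstage.experiments import staging_recovery_rate

        assert staging_recovery_rate(seed=101) >= 0.9
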