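"""Error taxonomy: wrapped errors, far-gap split, re-centering, labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crowdreport import (
    ONE_GAP, TWO_GAP, Condition, ObserverModel,
    compute_errors, label_proportions, nearest_model_label, recenter_far,
    sample_flanker_gaps, simulate_report, simulate_validation_dataset,
    split_far_gap, wrap_deg,
)


def _two_gap_frame(errors, delta2=None):
    n = len(errors)
    target = np.full(n, 100.0)
    df = pd.DataFrame({
        "observer_id": "S1", "session": 1, "flanker_type": TWO_GAP,
        "edge_separation_deg": 0.4, "target_deg": target,
        "gap1_deg": (target + 10) % 360,
        "gap2_deg": (target + (delta2 if delta2 is not None else 180)) % 360,
        "report_deg": (target + np.asarray(errors, dtype=float)) % 360,
    })
    return compute_errors(df)


class TestComputeErrors:
    @pytest.mark.parametrize("report, target, expected", [
        (10, 350, 20), (350, 10, -20), (123, 123, 0),
    ])
    def test_wrapped_difference(self, report, target, expected):
        df = pd.DataFrame({"observer_id": ["S1"], "session": [1],
                           "flanker_type": [ONE_GAP], "edge_separation_deg": [0.4],
                           "target_deg": [target], "gap1_deg": [np.nan],
                           "gap2_deg": [np.nan], "report_deg": [report]})
        out = compute_errors(df)
        assert out["error_deg"].iloc[0] == pytest.approx(expected)

    def test_missing_report_dropped_with_log(self, caplog):
        df = pd.DataFrame({"observer_id": ["S1", "S1"], "session": [1, 1],
                           "flanker_type": [ONE_GAP] * 2,
                           "edge_separation_deg": [0.4] * 2,
                           "target_deg": [0.0, 0.0], "gap1_deg": [20.0, 20.0],
                           "gap2_deg": [np.nan] * 2, "report_deg": [10.0, np.nan]})
        with caplog.at_level("WARNING"):
            out = compute_errors(df)
        assert len(out) == 1
        assert "dropping 1" in caplog.text


class TestFarGapSplit:
    def test_definition(self):
        near, far, split = split_far_gap(_two_gap_frame([0, 50, -120, 170]),
                                         n_boot=50, seed=0)
        assert list(split.is_far) == [False, False, True, True]
        assert split.proportion_far == pytest.approx(0.5)
        assert len(near) + len(far) == 4

    def test_all_near(self):
        _, far, split = split_far_gap(_two_gap_frame([0, 0, 0]), n_boot=50, seed=0)
        assert split.proportion_far == 0.0 and len(far) == 0

    def test_boundary_is_strict(self):
        near, far, _ = split_far_gap(_two_gap_frame([90, -90, 91]), n_boot=50, seed=0)
        assert len(near) == 2 and len(far) == 1

    def test_rejects_non_two_gap_trials(self):
        df = _two_gap_frame([0])
        df["flanker_type"] = ONE_GAP
        with pytest.raises(ValueError):
            split_far_gap(df)


class TestRecenterFar:
    @pytest.mark.parametrize("error, delta2, exp_error, exp_delta", [
        (170, 160, -10, -20), (-170, 170, 10, -10), (180, 180, 0, 0),
    ])
    def test_subtract_180(self, error, delta2, exp_error, exp_delta):
        _, far, _ = split_far_gap(_two_gap_frame([error], delta2=delta2),
                                  n_boot=50, seed=0)
        rc = recenter_far(far)
        assert rc["error_deg"].iloc[0] == pytest.approx(exp_error)
        assert rc["delta2_deg"].iloc[0] == pytest.approx(exp_delta)

    def test_requires_delta2(self):
        _, far, _ = split_far_gap(_two_gap_frame([170]), n_boot=50, seed=0)
        far["delta2_deg"] = np.nan
        with pytest.raises(ValueError):
            recenter_far(far)


class TestNearestModelLabel:
    @pytest.mark.parametrize("error, delta, expected", [
        (0, 40, "target"),          # distance 0
        (22, 40, "average"),        # distances 22, 2, 18
        (39, 40, "substitution"),   # distances 39, 19, 1
        (10, 40, "target"),         # 10 vs 10 tie -> priority target
        (30, 40, "average"),        # 30 vs 10 vs 10 tie -> priority average
    ])
    def test_examples(self, error, delta, expected):
        assert nearest_model_label(error, delta) == expected

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(-180, 180), st.floats(-180, 180))
    def test_matches_brute_force_oracle(self, error, delta):
        """Argmin over independently computed circular distances."""
        dists = {
            "target": abs(wrap_deg(error)),
            "average": abs(wrap_deg(error - delta / 2)),
            "substitution": abs(wrap_deg(error - delta)),
        }
        best = min(dists.values())
        # first label (in priority order) attaining the exact minimum
        expected = next(k for k in ("target", "average", "substitution")
                        if dists[k] == best)
        assert nearest_model_label(error, delta) == expected


class TestLabelProportions:
    def test_small_group(self):
        df = pd.DataFrame({
            "observer_id": "S1", "flanker_type": ONE_GAP,
            "edge_separation_deg": 0.4,
            "error_deg": [0.0, 1.0, 20.0, 39.0],
            "delta1_deg": [40.0] * 4,
        })
        out = label_proportions(df).proportions
        assert out[["p_target", "p_average", "p_substitution"]].iloc[0].tolist() == \
            pytest.approx([0.5, 0.25, 0.25])

    def test_proportions_sum_to_one(self):
        df = simulate_validation_dataset(0.5, 0.5, 15.0, n_trials=500, seed=8)
        out = label_proportions(df).proportions
        total = out[["p_target", "p_average", "p_substitution"]].sum(axis=1)
        assert np.allclose(total, 1.0)

    def test_pure_target_noise_free(self):
        df = simulate_validation_dataset(1.0, 0.0, 1e-6, n_trials=200, seed=9)
        out = label_proportions(df).proportions
        assert (out["p_target"] == 1.0).all()

    def test_recovers_known_mixture_with_separated_components(self, design, rng):
        """(0.4, 0.3, 0.3) mixture, SD 5 deg, delta fixed at 90 deg: labelled
        proportions land within 0.02 of the generative mixture."""
        model = ObserverModel(p_target=0.4, p_average=0.3, p_sub_near=0.3,
                              average_weight=0.5, noise_sd_deg=5.0)
        n = 10_000
        target = rng.uniform(0, 360, size=n)
        gap1 = (target + 90.0) % 360
        rows = []
        for t, g in zip(target, gap1):
            report, _ = simulate_report(t, g, np.nan, model, ONE_GAP, rng)
            rows.append(report)
        df = pd.DataFrame({
            "observer_id": "S1", "flanker_type": ONE_GAP,
            "edge_separation_deg": 0.4, "target_deg": target,
            "gap1_deg": gap1, "gap2_deg": np.nan, "report_deg": rows,
        })
        out = label_proportions(compute_errors(df)).proportions.iloc[0]
        assert out["p_target"] == pytest.approx(0.4, abs=0.02)
        assert out["p_average"] == pytest.approx(0.3, abs=0.02)
        assert out["p_substitution"] == pytest.approx(0.3, abs=0.02)

    def test_target_proportion_underestimated_when_others_absent(self):
        """With generative p_target = 1, experimental delta spread and noise
        SD 15 deg, nearest-model labelling assigns some pure-noise trials to
        average/substitution, so labelled p_target falls below 1."""
        df = simulate_validation_dataset(1.0, 0.0, 15.0, n_trials=5000, seed=10)
        out = label_proportions(df).proportions.iloc[0]
        assert out["p_target"] < 0.95

    def test_empty_group_reports_zero_n(self):
        df = simulate_validation_dataset(0.5, 0.5, 10.0, n_trials=10, seed=11)
        out = label_proportions(df.iloc[0:0])
        assert out.proportions.empty
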