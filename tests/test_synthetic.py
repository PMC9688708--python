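"""Synthetic cohort generator: planted structure, determinism, and
consistency between the time-series and direct-feature modes."""

import numpy as np
import pytest

from spaclust.features import auc_task_phase, baseline_level
from spaclust.methods import adjusted_rand_index, kmeans_labels
from spaclust.records import ALL_FEATURES, TIMESERIES_PARAMS
from spaclust.reduction import min_max_normalize, pca_project
from spaclust.synthetic import (
    CohortSpec,
    GroupTemplate,
    ProtocolSpec,
    component_separation_sd,
    default_cohort_spec,
    default_templates,
    generate_cohort,
    generate_feature_table,
    generate_subject,
    scale_template_contrast,
)

from conftest import BEST_COMBO


def quiet_template(amplitudes=None, **kw):
    """Template with all stochastic components switched off."""
    amps = {p: 0.0 for p in TIMESERIES_PARAMS}
    if amplitudes:
        amps.update(amplitudes)
    zeros = {p: 0.0 for p in TIMESERIES_PARAMS}
    defaults = dict(amplitude_sd=zeros, noise_sd=zeros, drift_sd=zeros,
                    onset_time_constant=1e-9)
    defaults.update(kw)
    return GroupTemplate(group_id="quiet", response_amplitude=amps, **defaults)


class TestProtocolAndTemplates:
    def test_default_protocol_matches_study_phases(self):
        p = ProtocolSpec()
        assert p.phase_bounds == (0.0, 480.0, 1020.0, 1920.0)
        assert p.sampling_rate == 1.0

    @pytest.mark.parametrize("field", ["baseline_duration", "task_duration",
                                       "recovery_duration", "sampling_rate"])
    def test_nonpositive_duration_rejected(self, field):
        with pytest.raises(ValueError):
            ProtocolSpec(**{field: 0.0})

    def test_template_must_cover_all_parameters(self):
        with pytest.raises(ValueError, match="missing amplitudes"):
            GroupTemplate(group_id="bad",
                          response_amplitude={"SC": 1.0})

    def test_default_group_counts(self):
        assert len(default_templates("blue")) == 3
        assert len(default_templates("red")) == 5


class TestGenerateSubject:
    def test_noise_free_plateau_matches_amplitude(self):
        tpl = quiet_template({"SC": 5.0})
        recs, _ = generate_subject(tpl, ProtocolSpec(),
                                   np.random.default_rng(0))
        sc = next(r for r in recs if r.parameter == "SC")
        base = baseline_level(sc)
        _, task = sc.window(481.0, 1020.0)  # past the (vanishing) onset
        assert np.allclose(task - base, 5.0, atol=1e-9)

    def test_zero_amplitudes_give_constant_channels(self):
        recs, _ = generate_subject(quiet_template(), ProtocolSpec(),
                                   np.random.default_rng(0))
        for rec in recs:
            assert np.ptp(rec.samples) == 0.0

    def test_same_rng_state_bit_identical(self):
        tpl = default_templates("blue")[0]
        a, pa = generate_subject(tpl, ProtocolSpec(), np.random.default_rng(7))
        b, pb = generate_subject(tpl, ProtocolSpec(), np.random.default_rng(7))
        assert pa == pb
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)


class TestGenerateCohort:
    def test_cohort_determinism_and_label_counts(self):
        spec = CohortSpec(n_subjects=12, seed=3)
        c1, c2 = generate_cohort(spec), generate_cohort(spec)
        for cond, maxg in (("blue", 3), ("red", 5)):
            np.testing.assert_array_equal(c1.per_condition[cond].labels,
                                          c2.per_condition[cond].labels)
            assert len(np.unique(c1.per_condition[cond].labels)) <= maxg
            assert set(c1.per_condition[cond].subject_ids) == \
                set(c2.per_condition[cond].subject_ids)
        s0 = c1.per_condition["blue"].records["s01"][0].samples
        np.testing.assert_array_equal(
            s0, c2.per_condition["blue"].records["s01"][0].samples)

    def test_adding_subjects_preserves_earlier_draws(self):
        small = generate_cohort(CohortSpec(n_subjects=8, seed=5))
        large = generate_cohort(CohortSpec(n_subjects=12, seed=5))
        np.testing.assert_array_equal(
            small.per_condition["red"].records["s05"][3].samples,
            large.per_condition["red"].records["s05"][3].samples)

    def test_degenerate_proportions_give_single_label(self):
        spec = CohortSpec(
            n_subjects=6, seed=0,
            group_proportions_per_condition={"blue": (1.0, 0.0, 0.0),
                                             "red": (1.0, 0.0, 0.0, 0.0, 0.0)})
        cohort = generate_cohort(spec)
        assert cohort.per_condition["blue"].n_groups_realized == 1
        assert set(cohort.per_condition["red"].labels.tolist()) == {0}

    def test_too_few_subjects_for_groups_rejected(self):
        with pytest.raises(ValueError, match="realize"):
            CohortSpec(n_subjects=4, seed=0)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(n_subjects=10, seed=0,
                       group_proportions_per_condition={
                           "blue": (0.5, 0.2, 0.2),
                           "red": (0.2,) * 5})


class TestFeatureTableMode:
    def test_shape_and_planted_component(self):
        tables, labels = generate_feature_table(default_cohort_spec(seed=2))
        for cond in ("blue", "red"):
            assert tables[cond].data.shape == (30, 15)
            assert list(tables[cond].data.columns) == list(ALL_FEATURES)
            assert len(labels[cond]) == 30

    def test_zero_separation_single_distribution(self):
        """With contrast removed, per-feature group means coincide."""
        spec = default_cohort_spec(seed=0, n_subjects=200)
        tables, labels = generate_feature_table(spec, separation=0.0)
        frame = tables["blue"].data
        for g in np.unique(labels["blue"]):
            mask = labels["blue"] == g
            if mask.sum() < 30:
                continue
            pooled = frame["SC"].to_numpy()
            assert abs(pooled[mask].mean() - pooled.mean()) < \
                3 * pooled.std() / np.sqrt(mask.sum())

    def test_zero_separation_recovery_at_chance(self):
        """k-means vs planted labels averages ARI ~ 0 over 50 cohorts."""
        aris = []
        for seed in range(50):
            spec = default_cohort_spec(seed=seed)
            tables, labels = generate_feature_table(spec, separation=0.0)
            norm = min_max_normalize(tables["blue"]).subset(BEST_COMBO)
            scores = pca_project(norm, 0.8).scores
            pred = kmeans_labels(scores, 3, seed=seed, n_init=10)
            aris.append(adjusted_rand_index(pred, labels["blue"]))
        assert abs(float(np.mean(aris))) < 0.1

    def test_large_separation_perfect_recovery(self):
        """Components >= 6 SD apart: k-means at true k recovers exactly."""
        for seed in range(20):
            spec = default_cohort_spec(seed=seed, separation=2.0)
            assert component_separation_sd(spec, "blue", features=BEST_COMBO) >= 6
            assert component_separation_sd(spec, "red", features=BEST_COMBO) >= 6
            tables, labels = generate_feature_table(spec)
            for cond, k in (("blue", 3), ("red", 5)):
                norm = min_max_normalize(tables[cond]).subset(BEST_COMBO)
                scores = pca_project(norm, 0.8).scores
                pred = kmeans_labels(scores, k, seed=seed, n_init=10)
                assert adjusted_rand_index(pred, labels[cond]) == 1.0


class TestModeConsistency:
    def test_auc_converges_to_amplitude_times_duration(self):
        """Noise-free time series: extracted AUC equals amplitude x task
        duration up to the onset-transient correction ~ tau * amplitude."""
        protocol = ProtocolSpec()
        tpl = quiet_template({"SC": 4.0, "HR": -3.0},
                             onset_time_constant=30.0)
        recs, _ = generate_subject(tpl, protocol, np.random.default_rng(0))
        for param, amp in (("SC", 4.0), ("HR", -3.0)):
            rec = next(r for r in recs if r.parameter == param)
            auc = auc_task_phase(rec, baseline_level(rec))
            # onset transient removes ~tau*amp of area; the trapezoidal
            # grid adds a sub-sample-width correction on top
            assert abs(auc - amp * protocol.task_duration) <= \
                30.0 * abs(amp) + 0.1

    def test_contrast_scaling_is_linear_around_mean(self):
        tpls = default_templates("blue")
        doubled = scale_template_contrast(tpls, 2.0)
        mean_sc = np.mean([t.response_amplitude["SC"] for t in tpls])
        for t0, t2 in zip(tpls, doubled):
            assert t2.response_amplitude["SC"] == pytest.approx(
                mean_sc + 2.0 * (t0.response_amplitude["SC"] - mean_sc))
        collapsed = scale_template_contrast(tpls, 0.0)
        assert len({t.response_amplitude["SC"] for t in collapsed}) == 1
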