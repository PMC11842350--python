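import numpy as np
import pandas as pd
import pytest

from liftrisk.io import Trial
from liftrisk.risk_analysis import (
    cluster_loads,
    cluster_separation_tests,
    normality_test,
    summarize_trial,
    summaries_to_frame,
    wilcoxon_pairwise,
)
from liftrisk.signals import LiftCycle, TimeSeries
from liftrisk.trunk_model import JointLoadSeries

FS = 340.0


def make_loads(n, moment=2.0, compression=5.0, shear=0.5):
    ones = np.ones(n)
    return JointLoadSeries(
        fs=FS, t0=0.0, moment=moment * 80 * ones, compression=compression * ones,
        shear=shear * ones, moment_norm=moment * ones,
        compression_bw=compression * ones, shear_bw=shear * ones,
    )


def make_trial(n, angle):
    return Trial(
        subject_id="S1", risk_level=1, repetition=1, load_mass=21.0,
        fs_motion=FS, fs_emg=1000.0, box_height=np.zeros(n),
        box_velocity=np.zeros(n), angle=angle, load_force=np.zeros(n),
    )


def envelope(values, fs=1000.0):
    return TimeSeries(values=np.asarray(values, dtype=float), fs=fs)


class TestSummarize:
    def test_constant_loads_peak_is_constant(self):
        n = 680
        cycle = LiftCycle(start_index=100, end_index=500, fs=FS)
        trial = make_trial(n, np.zeros(n))
        env = {
            "erector_spinae_longissimus_left": envelope(np.full(2000, 0.4)),
            "erector_spinae_longissimus_right": envelope(np.full(2000, 0.6)),
        }
        s = summarize_trial(trial, make_loads(n), env, cycle)
        assert s.peak_compression_bw == pytest.approx(5.0)
        assert s.peak_moment_norm == pytest.approx(2.0)
        # left/right peaks averaged after extraction
        assert s.peak_emg["longissimus"] == pytest.approx(0.5)

    def test_rom_of_45_degree_arc(self):
        n = 680
        t = np.arange(n) / FS
        angle = np.deg2rad(45.0) * np.sin(np.pi * t / t[-1]) ** 2
        cycle = LiftCycle(start_index=0, end_index=n - 1, fs=FS)
        s = summarize_trial(make_trial(n, angle), make_loads(n), {}, cycle)
        assert s.rom_deg == pytest.approx(45.0, abs=0.1)

    def test_samples_outside_cycle_ignored(self):
        n = 680
        loads = make_loads(n)
        loads.compression_bw[10] = 99.0  # spike before the lift starts
        cycle = LiftCycle(start_index=100, end_index=500, fs=FS)
        s = summarize_trial(make_trial(n, np.zeros(n)), loads, {}, cycle)
        assert s.peak_compression_bw == pytest.approx(5.0)

    def test_unnormalized_loads_rejected(self):
        n = 200
        loads = JointLoadSeries(fs=FS, t0=0.0, moment=np.ones(n),
                                compression=np.ones(n), shear=np.ones(n))
        cycle = LiftCycle(start_index=0, end_index=n - 1, fs=FS)
        with pytest.raises(ValueError):
            summarize_trial(make_trial(n, np.zeros(n)), loads, {}, cycle)


class TestNormality:
    def test_calibrated_on_normal_draws(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(10.0, 2.0, 500)
            _, p = normality_test(x)
            hits += p > 0.05
        assert hits >= 90

    def test_detects_bimodality(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(0, 1, 250), rng.normal(8, 1, 250)])
            _, p = normality_test(x)
            rejections += p < 0.05
        assert rejections >= 18

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test(np.full(20, 3.0))

    def test_unsupported_size_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


def paired_frame(level_values, n_subjects=7, n_reps=3, noise_sd=0.0, seed=0):
    """Summaries frame with one metric, built per (subject, repetition)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for rep in range(n_reps):
            for level, base in level_values.items():
                rows.append(
                    {"subject_id": f"S{s}", "repetition": rep, "risk_level": level,
                     "metric": base + 0.3 * s + 0.1 * rep + rng.normal(0, noise_sd)}
                )
    return pd.DataFrame(rows)


class TestWilcoxon:
    def test_identical_levels_degenerate(self):
        frame = paired_frame({1: 5.0, 2: 5.0, 3: 5.0})
        table = wilcoxon_pairwise(frame, "metric")
        assert (table["z"] == 0.0).all()
        assert (table["p_adjusted"] == 1.0).all()

    def test_constant_shift_detected_at_n21(self):
        # all 21 pairs tied in |difference|: significant via the normal
        # approximation, well past the Bonferroni-corrected threshold
        frame = paired_frame({1: 5.0, 2: 6.0, 3: 7.0})
        table = wilcoxon_pairwise(frame, "metric")
        assert (table["n"] == 21).all()
        assert (table["p_adjusted"] < 0.05).all()
        # lower level smaller -> negative z, matching the reporting convention
        assert (table["z"] < 0).all()

    def test_distinct_one_sided_shifts_reach_exact_floor_at_n21(self):
        # distinct same-sign differences: the exact two-sided signed-rank
        # p for n = 21 is 2 * 2^-21 = 2^-20, the minimal attainable value
        rng = np.random.default_rng(4)
        frame = paired_frame({1: 5.0, 2: 5.0, 3: 5.0})
        bump = {2: 1.0, 3: 2.0}
        jitter = 0.01 * rng.random(len(frame))
        frame["metric"] = frame["metric"] + frame["risk_level"].map(
            lambda lvl: bump.get(lvl, 0.0)
        ) + jitter
        table = wilcoxon_pairwise(frame, "metric")
        assert table["p_raw"].max() == pytest.approx(2.0 ** -20, rel=1e-6)
        assert np.allclose(table["p_adjusted"], 3 * 2.0 ** -20, rtol=1e-6)

    def test_bonferroni_never_decreases_p(self):
        frame = paired_frame({1: 5.0, 2: 5.5, 3: 6.5}, noise_sd=1.0, seed=3)
        table = wilcoxon_pairwise(frame, "metric")
        assert (table["p_adjusted"] >= table["p_raw"]).all()
        assert (table["p_adjusted"] <= 1.0).all()

    def test_unmatched_pairing_rejected(self):
        frame = paired_frame({1: 5.0, 2: 6.0, 3: 7.0})
        frame = frame.drop(frame[(frame.subject_id == "S0")
                                 & (frame.risk_level == 2)
                                 & (frame.repetition == 0)].index)
        with pytest.raises(ValueError):
            wilcoxon_pairwise(frame, "metric")


def blob_frame(centers, n_per=10, sd=0.02, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, (m, c) in enumerate(centers):
        for _ in range(n_per):
            rows.append(
                {"subject_id": "S1", "repetition": 1, "risk_level": (i % 3) + 1,
                 "peak_moment_norm": rng.normal(m, sd),
                 "peak_compression_bw": rng.normal(c, sd)}
            )
    return pd.DataFrame(rows)


class TestClustering:
    def test_two_well_separated_blobs_partitioned_exactly(self):
        frame = blob_frame([(2.0, 5.0), (4.0, 10.0)], n_per=12)
        report = cluster_loads(frame, k=2, seed=0, scan_k=None)
        labels = report.assignments
        assert set(labels[:12]) == {1} and set(labels[12:]) == {2}

    def test_centroid_compression_increases_with_label(self):
        frame = blob_frame([(2, 5), (2.5, 6), (3, 7), (3.5, 8)], n_per=8)
        report = cluster_loads(frame, k=4, seed=0, scan_k=None)
        comp = report.centroids["peak_compression_bw"].to_numpy()
        assert np.all(np.diff(comp) > 0)

    def test_crosstab_rows_sum_to_trials_per_level(self):
        frame = blob_frame([(2, 5), (3, 7), (4, 9)], n_per=9)
        report = cluster_loads(frame, k=3, seed=0, scan_k=None)
        counts = frame.groupby("risk_level").size()
        for level, total in counts.items():
            assert report.crosstab.loc[level].sum() == total
        assert len(report.assignments) == len(frame)

    def test_default_six_clusters_give_fifteen_pairs(self):
        frame = blob_frame([(2, 5), (2.4, 6), (2.8, 7), (3.2, 8), (3.6, 9), (4, 10)],
                           n_per=6)
        report = cluster_loads(frame, k=6, seed=0, scan_k=None)
        assert report.k == 6
        assert len(report.ttests) == 15

    def test_more_clusters_than_trials_rejected(self):
        frame = blob_frame([(2, 5)], n_per=3)
        with pytest.raises(ValueError):
            cluster_loads(frame, k=5, seed=0, scan_k=None)


class TestSeparationTests:
    def test_identical_clusters_t_near_zero(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(5, 1, 40), rng.normal(5, 1, 40)])
        labels = np.array([1] * 40 + [2] * 40)
        t = cluster_separation_tests(labels, values)["t"].iloc[0]
        assert abs(t) < 2.0

    def test_known_separation_t_statistic(self):
        # means 1 vs 2, sd 0.1, n = 10 each -> |t| = 1 / sqrt(2*0.01/10) = 22.36
        rng = np.random.default_rng(1)
        a = 1.0 + 0.1 * rng.standard_normal(10)
        b = 2.0 + 0.1 * rng.standard_normal(10)
        a = (a - a.mean()) / a.std(ddof=1) * 0.1 + 1.0
        b = (b - b.mean()) / b.std(ddof=1) * 0.1 + 2.0
        table = cluster_separation_tests(
            np.array([1] * 10 + [2] * 10), np.concatenate([a, b])
        )
        assert table["t"].iloc[0] == pytest.approx(-22.36, abs=0.01)

    def test_singleton_cluster_excluded_with_warning(self):
        values = np.array([1.0, 1.1, 1.2, 5.0])
        labels = np.array([1, 1, 1, 2])
        with pytest.warns(UserWarning):
            table = cluster_separation_tests(labels, values)
        assert len(table) == 0


def test_summaries_frame_round_trip(small_dataset):
    from liftrisk.pipeline import estimate_loads, process_trial
    from liftrisk.synthetic_data import apply_scales
    from liftrisk.trunk_model import default_groups

    subject = small_dataset.subjects[0]
    groups = apply_scales(default_groups(),
                          small_dataset.subject_scales[subject.subject_id])
    summaries = []
    for trial in small_dataset.trials_for(subject.subject_id)[:4]:
        p = estimate_loads(process_trial(trial, subject), subject, groups)
        summaries.append(p.summary)
    frame = summaries_to_frame(summaries)
    assert len(frame) == 4
    assert {"peak_moment_norm", "peak_compression_bw", "rom_deg"} <= set(frame.columns)
    assert frame["peak_compression_bw"].gt(0).all()
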