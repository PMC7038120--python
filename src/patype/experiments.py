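"""Scenario drivers: reusable study-scale computations.

These functions tie the generator, preprocessing, feature extraction and
classification together into the evaluations the package is built to run:
cross-subject (L1SO) versus segment-wise (k-fold) validation, the
accelerometer-only versus accelerometer+GPS comparison, synchronization
recovery, ramp-grade recovery, and the segment-size sensitivity sweep.

Forest sizes and cohort sizes default to values chosen to characterize the
pipeline well on a single CPU; both are parameters.
"""
from __future__ import annotations

import numpy as np

from . import accel
from .classify import ModelSpec, kfold_cv, loso_cv, segment_size_sensitivity
from .gps import preprocess_track
from .pipeline import build_feature_table
from .synthetic import (
    GapSpec,
    default_protocols,
    generate_cohort,
    generate_participant,
    generate_terrain,
    random_profile,
    simulate_gps,
)


def _child_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, salt]).generate_state(1)[0] & 0x7FFFFFFF)


def run_study(
    seed: int,
    n_subjects: int = 10,
    window_s: float = 10.0,
    n_trees: int = 100,
    task_duration: float = 60.0,
    scenario: str = "S2_combined",
    k: int = 10,
) -> dict:
    """One full study replicate at the default synthetic conditions.

    Generates a cohort, runs the full preprocessing + feature pipeline, and
    evaluates the general model three ways: L1SO with accelerometer
    features only, L1SO with accelerometer + GPS features, and segment-wise
    stratified k-fold with accelerometer features.  Returns the three
    EvaluationReports plus the feature table.
    """
    cohort = generate_cohort(n_subjects=n_subjects, seed=seed, task_duration=task_duration)
    features = build_feature_table(cohort, window_s=window_s)
    rf_seed = _child_seed(seed, 1)
    spec_acc = ModelSpec(scope="general", feature_set="acc", scenario=scenario,
                         window_s=window_s, n_trees=n_trees, seed=rf_seed)
    spec_gps = ModelSpec(scope="general", feature_set="acc_gps", scenario=scenario,
                         window_s=window_s, n_trees=n_trees, seed=rf_seed)
    return {
        "cohort": cohort,
        "features": features,
        "loso_acc": loso_cv(features, spec_acc),
        "loso_acc_gps": loso_cv(features, spec_gps),
        "kfold_acc": kfold_cv(features, spec_acc, k=k, seed=rf_seed),
    }


def run_battery(seed: int, n_seeds: int = 5, **kwargs) -> list:
    """Independent study replicates with seeds derived from `seed`."""
    return [run_study(_child_seed(seed, 100 + i), **kwargs) for i in range(n_seeds)]


def sync_recovery_errors(seed: int, n_trials: int = 20) -> np.ndarray:
    """Max absolute synchronization error (s) per trial over random offsets.

    Each trial generates a short participant with fresh clock offsets in
    +/- 2 s, recovers them from the jump markers, and compares against the
    generator's ground truth.
    """
    terrain = generate_terrain(seed=seed)
    protocols = default_protocols(task_duration=30.0)
    protocols = [type(p)(p.protocol, p.tasks[:2], gps_gap_rate=0.0) for p in protocols[:1]]
    errors = []
    for i in range(n_trials):
        trial_seed = _child_seed(seed, 200 + i)
        rng = np.random.default_rng(trial_seed)
        profile = random_profile(f"T{i:02d}", rng)
        p = generate_participant(profile, protocols, terrain, seed=trial_seed)
        cleaned = {pos: accel.clean_stream(s) for pos, s in p.streams.items()}
        _, shifts = accel.synchronize(cleaned, reference="chest")
        err = max(abs(shifts[pos] + p.clock_offsets[pos]) for pos in shifts)
        errors.append(err)
    return np.array(errors)


def ramp_grade_error(seed: int, grade_pct: float = 10.0, duration: float = 120.0) -> dict:
    """Recover a ramp's grade from a noisy GPS walk after the full GPS chain.

    Simulates uphill walking on a ramp road, runs cleaning, interpolation,
    map matching, DEM sampling and smoothing, then estimates grade as the
    smoothed elevation difference over the net along-track displacement
    (summing per-fix steps would count the back-and-forth of residual
    along-road jitter as distance).
    """
    terrain = generate_terrain(slope_spec="ramp", grade_pct=grade_pct, seed=seed)
    rng = np.random.default_rng(_child_seed(seed, 300))
    profile = random_profile("G01", rng)
    track = simulate_gps(
        [("walking_uphill", duration)], terrain, profile, gap_spec=GapSpec(), seed=_child_seed(seed, 301)
    )
    processed = preprocess_track(track, terrain, motion_mask_fn=lambda t: np.ones(len(t), bool))
    elev = processed["dem_elevation_smooth"].to_numpy()
    x = processed["x_m"].to_numpy()
    y = processed["y_m"].to_numpy()
    dist = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    grade_hat = 100.0 * (elev[-1] - elev[0]) / dist
    return {
        "grade_true_pct": grade_pct,
        "grade_est_pct": grade_hat,
        "rel_error": abs(grade_hat - grade_pct) / grade_pct,
    }


def sensitivity_study(
    seed: int,
    n_subjects: int = 5,
    sizes=accel.WINDOW_SIZES_S,
    n_trees: int = 100,
    scenario: str = "S1_semi_structured",
):
    """Segment-size sweep: L1SO accuracy of the general ACC model per size."""
    specs = default_protocols(task_duration=60.0)[:1]  # semi-structured session
    cohort = generate_cohort(n_subjects=n_subjects, seed=seed, protocol_specs=specs)
    spec = ModelSpec(scope="general", feature_set="acc", scenario=scenario,
                     n_trees=n_trees, seed=_child_seed(seed, 2))
    return segment_size_sensitivity(cohort, spec, sizes=sizes)
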