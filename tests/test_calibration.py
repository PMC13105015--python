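"""Local posterior curves, bootstrap bounds, threshold extraction."""

import numpy as np
import pytest

from indelcal import (
    ConfigurationError,
    InputError,
    PointScale,
    PosteriorCurve,
    ScoreSet,
    WindowRule,
    bootstrap_bounds,
    calibrate_tool,
    estimate_posterior_curve,
    extract_thresholds,
    local_posterior_at,
    orient_scores,
    posterior_threshold_for_level,
)

SEED = 12345


def _score_set(path, benign, direction="higher_pathogenic", vtype="deletion"):
    return ScoreSet(
        tool="t",
        variant_type=vtype,
        direction=direction,
        pathogenic_scores=np.asarray(path, dtype=float),
        benign_scores=np.asarray(benign, dtype=float),
    )


def test_orient_scores_involution_and_negation():
    s = _score_set([-23.07, -5.0], [1.0, 2.0], direction="lower_pathogenic")
    once = orient_scores(s)
    assert once.oriented
    assert np.allclose(once.pathogenic_scores, [23.07, 5.0])
    twice = orient_scores(once)
    assert np.allclose(twice.pathogenic_scores, s.pathogenic_scores)
    higher = _score_set([1.0], [0.0])
    assert np.allclose(orient_scores(higher).pathogenic_scores, higher.pathogenic_scores)


def test_local_posterior_hand_arithmetic():
    # 30/100 pathogenic and 10/100 benign inside the window at prior 0.046:
    # (0.046*0.3) / (0.046*0.3 + 0.954*0.1) = 0.0138 / 0.1092
    rng = np.random.default_rng(0)
    path = np.concatenate([rng.uniform(-0.1, 0.1, 30), np.full(70, 100.0)])
    ben = np.concatenate([rng.uniform(-0.1, 0.1, 10), np.full(90, 100.0)])
    post, eps, c_p, c_b = local_posterior_at(
        0.0, _score_set(path, ben), 0.046, WindowRule(min_count=40)
    )
    assert (c_p, c_b) == (30, 10)
    assert post == pytest.approx(0.0138 / 0.1092, abs=1e-9)
    assert eps <= 0.11


def test_posterior_is_one_in_pathogenic_only_window():
    path = np.linspace(10, 11, 50)
    ben = np.linspace(-11, -10, 50)
    post, _, c_p, c_b = local_posterior_at(
        10.5, _score_set(path, ben), 0.046, WindowRule(min_count=20)
    )
    assert c_b == 0 and post == 1.0


def test_identical_samples_recover_the_prior_exactly():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=2000)
    s = _score_set(scores, scores.copy())
    for prior in (0.008, 0.046, 0.3):
        curve = estimate_posterior_curve(s, prior, WindowRule(grid_size=201))
        assert np.allclose(curve.estimate, prior, atol=1e-12)


def test_prior_to_one_limit():
    rng = np.random.default_rng(6)
    s = _score_set(rng.normal(2, 1, 500), rng.normal(0, 1, 500))
    curve = estimate_posterior_curve(s, 0.999, WindowRule(grid_size=101))
    has_path = curve.c_path > 0
    assert np.all(curve.estimate[has_path] > 0.9)
    # where pathogenic density dominates, the estimate is essentially 1
    dominant = has_path & (curve.c_path >= curve.c_benign)
    assert np.all(curve.estimate[dominant] > 0.999)


def test_curve_tracks_analytic_posterior(gaussian_truth, gaussian_scores_large):
    curve = estimate_posterior_curve(gaussian_scores_large, 0.046, WindowRule())
    p, b = gaussian_scores_large.pathogenic_scores, gaussian_scores_large.benign_scores
    lo = max(np.percentile(p, 5), np.percentile(b, 5))
    hi = min(np.percentile(p, 95), np.percentile(b, 95))
    mask = (curve.grid >= lo) & (curve.grid <= hi)
    err = np.abs(curve.estimate[mask] - gaussian_truth.analytic_posterior(curve.grid[mask]))
    assert err.max() <= 0.05


def test_degenerate_score_range_single_point_curve():
    s = _score_set([1.0, 1.0], [1.0, 1.0])
    with pytest.warns(UserWarning, match="degenerate"):
        curve = estimate_posterior_curve(s, 0.046)
    assert curve.grid.size == 1


def test_window_counts_meet_min_count_away_from_saturation():
    rng = np.random.default_rng(8)
    s = _score_set(rng.normal(2, 1, 1000), rng.normal(0, 1, 1000))
    curve = estimate_posterior_curve(s, 0.046, WindowRule(min_count=100, grid_size=301))
    assert np.all(curve.c_path + curve.c_benign >= 100)


def test_bootstrap_single_replicate_bounds_coincide():
    rng = np.random.default_rng(9)
    s = _score_set(rng.normal(2, 1, 300), rng.normal(0, 1, 300))
    curve = bootstrap_bounds(s, 0.046, WindowRule(grid_size=101), B=1, seed=3)
    assert np.allclose(curve.lower, curve.upper)


def test_bootstrap_requires_seed():
    s = _score_set([1.0, 2.0], [0.0, 0.5])
    with pytest.raises(ConfigurationError, match="seed"):
        bootstrap_bounds(s, 0.046, B=2)


def test_degenerate_composition_pins_the_bound():
    s = _score_set(np.full(50, 1.0), np.zeros(50))
    curve = bootstrap_bounds(s, 0.046, WindowRule(min_count=10, grid_size=11), B=25, seed=4)
    # resampling cannot change the all-pathogenic composition at the top score
    assert curve.lower[-1] == 1.0


def test_bootstrap_lower_bound_mostly_below_estimate():
    rng = np.random.default_rng(10)
    s = _score_set(rng.normal(2, 1, 1000), rng.normal(0, 1, 1000))
    curve = bootstrap_bounds(s, 0.046, WindowRule(grid_size=201), B=200, seed=SEED)
    frac = np.mean(curve.lower <= curve.estimate + 1e-9)
    assert frac >= 0.99


def _step_curve(grid, crossing, high, low=0.0, prior=0.046):
    """Synthetic monotone bound stepping from low to high at `crossing`."""
    vals = np.where(grid >= crossing, high, low)
    pooled = np.sort(np.concatenate([grid, grid]))  # dense support everywhere
    return PosteriorCurve(
        grid=grid,
        estimate=vals,
        half_width=np.zeros_like(grid),
        c_path=np.ones_like(grid, dtype=int),
        c_benign=np.ones_like(grid, dtype=int),
        pooled_scores=pooled,
        settings={
            "prior": prior,
            "tool": "step",
            "variant_type": "deletion",
            "direction": "higher_pathogenic",
        },
        lower=vals,
        upper=vals,
    )


def test_step_bound_threshold_extracted_exactly():
    grid = np.round(np.linspace(0.0, 3.0, 301), 10)  # 1.30 lies on the grid
    bar = posterior_threshold_for_level(0.046, 1)
    curve = _step_curve(grid, crossing=1.30, high=bar + 0.01)
    thr = extract_thresholds(curve, PointScale.from_prior(0.046), min_support=1)
    # pathogenic side: exactly +1 (the flat prefix at 0 legitimately attains benign levels)
    assert [k for k in thr.attained_levels if k > 0] == [1]
    assert thr.threshold_score(1) == pytest.approx(1.30, abs=1e-9)
    # bound never attains +2, so +2 is absent rather than extrapolated
    assert 2 not in thr.intervals


def test_unsupported_extreme_level_excluded():
    grid = np.linspace(0.0, 3.0, 301)
    bar3 = posterior_threshold_for_level(0.046, 3)
    curve = _step_curve(grid, crossing=1.0, high=bar3 + 0.01)
    # gut the pooled support above the +3 threshold region
    curve.pooled_scores = np.sort(np.concatenate([np.linspace(0, 0.99, 600), [2.9] * 5]))
    thr = extract_thresholds(curve, PointScale.from_prior(0.046), min_support=10)
    excluded = dict(thr.excluded)
    assert 3 in excluded and "support" in excluded[3]
    assert 3 not in thr.intervals


def test_scale_prior_must_match_curve_prior():
    grid = np.linspace(0, 1, 51)
    curve = _step_curve(grid, 0.5, 0.5)
    with pytest.raises(InputError, match="prior"):
        extract_thresholds(curve, PointScale.from_prior(0.3))


def _calibrated(prior, B=200, seed=SEED, n=2000, direction="higher_pathogenic"):
    rng = np.random.default_rng(77)
    sign = 1.0 if direction == "higher_pathogenic" else -1.0
    s = _score_set(sign * rng.normal(2, 1, n), sign * rng.normal(0, 1, n), direction=direction)
    curve = bootstrap_bounds(s, prior, WindowRule(grid_size=401), B=B, seed=seed)
    scale = PointScale.from_prior(prior)
    return curve, scale


def test_stringent_thresholds_at_least_as_extreme_as_estimate():
    curve, scale = _calibrated(0.046)
    stringent = extract_thresholds(curve, scale)
    estimate = extract_thresholds(curve, scale, bound="estimate")
    for k in stringent.attained_levels:
        if k not in estimate.intervals:
            continue
        if k > 0:
            assert stringent.threshold_score(k) >= estimate.threshold_score(k) - 1e-9
        else:
            assert stringent.threshold_score(k) <= estimate.threshold_score(k) + 1e-9


def test_interval_coherence_disjoint_ordered_boundary_to_stronger():
    curve, scale = _calibrated(0.046)
    thr = extract_thresholds(curve, scale)
    assert thr.attained_levels  # sanity: some evidence attained
    for k in thr.attained_levels:
        iv = thr.intervals[k]
        # each level's own threshold maps back to that level (stronger-level rule)
        assert thr.assign(thr.threshold_score(k)) == k
        assert iv.low < iv.high
    # disjointness on a dense probe
    probes = np.linspace(curve.grid[0] - 1, curve.grid[-1] + 1, 2000)
    for x in probes:
        hits = [iv.level for iv in thr.intervals.values() if iv.contains(x)]
        assert len(hits) <= 1


def test_lower_prior_never_relaxes_thresholds():
    prev = None
    for prior in (0.2, 0.046, 0.008):
        curve, scale = _calibrated(prior)
        thr = extract_thresholds(curve, scale)
        if prev is not None:
            for k in thr.attained_levels:
                if k not in prev.intervals:
                    continue
                if k > 0:
                    assert thr.threshold_score(k) >= prev.threshold_score(k) - 1e-9
                else:
                    assert thr.threshold_score(k) <= prev.threshold_score(k) + 1e-9
        prev = thr


def test_calibration_deterministic_under_seed():
    c1, scale = _calibrated(0.046, B=50)
    c2, _ = _calibrated(0.046, B=50)
    assert np.array_equal(c1.lower, c2.lower)
    t1 = extract_thresholds(c1, scale)
    t2 = extract_thresholds(c2, scale)
    assert t1.to_frame().equals(t2.to_frame())


def test_lower_pathogenic_direction_round_trips_to_original_units():
    curve, scale = _calibrated(0.046, direction="lower_pathogenic")
    thr = extract_thresholds(curve, scale)
    assert thr.direction == "lower_pathogenic"
    for k in thr.attained_levels:
        # pathogenic evidence sits at the low end of the original axis
        t = thr.threshold_score(k)
        assert thr.assign(t) == k
        if k > 0:
            assert thr.assign(t + 0.5) in (0, *[x for x in thr.attained_levels if x < k])


def test_calibrate_tool_runs_types_independently():
    rng = np.random.default_rng(13)
    path, ben = rng.normal(2, 1, 800), rng.normal(0, 1, 800)
    make = lambda vtype: _score_set(path, ben, vtype=vtype)
    with pytest.warns(UserWarning, match="insertion"):
        only_del = calibrate_tool(
            None, make("deletion"), None, 0.046,
            rule=WindowRule(grid_size=201), B=50, seed=SEED,
        )
    assert set(only_del) == {"deletion"}
    both = calibrate_tool(
        make("insertion"), make("deletion"), 0.008, 0.046,
        rule=WindowRule(grid_size=201), B=50, seed=SEED,
    )
    assert set(both) == {"insertion", "deletion"}
    # identical data, lower insertion prior: insertion thresholds at least as extreme
    ins, dele = both["insertion"].thresholds, both["deletion"].thresholds
    for k in set(ins.attained_levels) & set(dele.attained_levels):
        if k > 0:
            assert ins.threshold_score(k) >= dele.threshold_score(k) - 1e-9
        else:
            assert ins.threshold_score(k) <= dele.threshold_score(k) + 1e-9
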