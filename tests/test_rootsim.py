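import numpy as np
import pytest
from scipy import stats

from rootpheno.sim import RootParams, simulate_root_system, true_traits
from rootpheno.sim.roots import STEP_CM, Lateral, RootSystemTruth

from conftest import straight_params


def straight_polyline(start, angle_deg, length_cm):
    """Straight polyline at a fixed angle from vertical, STEP_CM vertices."""
    n = int(round(length_cm / STEP_CM))
    t = STEP_CM * np.arange(n + 1)
    rad = np.deg2rad(angle_deg)
    return np.column_stack([start[0] + t * np.sin(rad), start[1] + t * np.cos(rad)])


def test_noise_free_limit_is_a_straight_vertical_segment():
    truth = simulate_root_system(straight_params(), days=(12, 15))
    tt = true_traits(truth, 15)
    assert truth.primary_polyline[:, 0] == pytest.approx(0.0)
    assert tt["PRL"] == pytest.approx(2.0 * 15, abs=STEP_CM)
    assert tt["TRL"] == pytest.approx(tt["PRL"])
    assert tt["LRB"] == 0
    assert tt["WID"] == pytest.approx(0.08)  # silhouette width = diameter
    assert tt["DEP"] == pytest.approx(30.0 + 0.08, abs=STEP_CM)  # plus end caps


def test_degenerate_angle_distribution_gives_exact_emergence_angles():
    p = straight_params(lateral_rate_per_cm=0.5, lateral_angle_mean_deg=40.0)
    truth = simulate_root_system(p, days=(12, 15))
    assert truth.laterals
    for lat in truth.laterals:
        assert lat.emergence_angle_deg == pytest.approx(40.0)
        d = np.diff(lat.polyline[:2], axis=0)[0] if len(lat.polyline) > 1 else None
        if d is not None:
            ang = np.degrees(np.arctan2(abs(d[0]), d[1]))
            assert ang == pytest.approx(40.0, abs=1e-9)


def test_lateral_count_matches_poisson_mean():
    # rate 2 per cm on a ~42 cm primary: empirical mean within 3 SE of rate*length
    counts = []
    for seed in range(100):
        p = straight_params(seed=seed, lateral_rate_per_cm=2.0, primary_rate=2.8, lateral_rate=0.05)
        truth = simulate_root_system(p, days=(15,))
        counts.append(len(truth.laterals))
    lam = 2.0 * 2.8 * 15
    se = np.sqrt(lam / len(counts))
    assert abs(np.mean(counts) - lam) < 3 * se


def test_lateral_counts_are_poisson_by_chisquare():
    """Chi-square goodness of fit of total emergence counts to Poisson."""
    lam = 2.0 * 2.0 * 5  # rate * primary_rate * days
    counts = np.array(
        [
            len(
                simulate_root_system(
                    straight_params(seed=s, lateral_rate_per_cm=2.0, lateral_rate=0.02),
                    days=(5,),
                ).laterals
            )
            for s in range(500)
        ]
    )
    lo, hi = int(stats.poisson.ppf(0.005, lam)), int(stats.poisson.ppf(0.995, lam))
    edges = np.arange(lo, hi + 1)
    obs = np.array([(counts == k).sum() for k in edges], dtype=float)
    obs = np.concatenate([[np.sum(counts < lo)], obs, [np.sum(counts > hi)]])
    pmf = stats.poisson.pmf(edges, lam)
    exp = np.concatenate([[stats.poisson.cdf(lo - 1, lam)], pmf, [stats.poisson.sf(hi, lam)]])
    exp = exp * len(counts)
    # pool sparse bins to keep expected counts reasonable
    keep = exp >= 2
    obs = np.concatenate([obs[keep], [obs[~keep].sum()]])
    exp = np.concatenate([exp[keep], [exp[~keep].sum()]])
    chi2 = ((obs - exp) ** 2 / exp).sum()
    p = stats.chi2.sf(chi2, df=len(obs) - 1)
    assert p > 0.01


def test_true_lra_is_median_of_lateral_angles():
    primary = straight_polyline((0.0, 0.0), 0.0, 30.0)
    laterals = [
        Lateral(10.0, 1, straight_polyline((0.0, 10.0), 40.0, 5.0), 40.0),
        Lateral(20.0, 1, straight_polyline((0.0, 20.0), 60.0, 5.0), 60.0),
    ]
    truth = RootSystemTruth(
        primary_polyline=primary,
        laterals=laterals,
        days=(15,),
        params=straight_params(lateral_rate=1.0),
    )
    tt = true_traits(truth, 15)
    assert tt["LRA"] == pytest.approx(50.0, abs=1e-9)
    assert tt["LRB"] == 2


def test_trl_at_least_prl_for_random_parameters():
    for seed in range(5):
        p = RootParams(seed=seed)
        truth = simulate_root_system(p, days=(12, 15, 18))
        for day in (12, 15, 18):
            tt = true_traits(truth, day)
            assert tt["TRL"] >= tt["PRL"] > 0
            assert tt["TRL_Upper"] + tt["TRL_Lower"] == pytest.approx(tt["TRL"])


def test_simulation_deterministic_given_seed():
    a = simulate_root_system(RootParams(seed=11), days=(12, 15))
    b = simulate_root_system(RootParams(seed=11), days=(12, 15))
    assert np.array_equal(a.primary_polyline, b.primary_polyline)
    assert len(a.laterals) == len(b.laterals)
    for la, lb in zip(a.laterals, b.laterals):
        assert np.array_equal(la.polyline, lb.polyline)


def test_unsorted_days_rejected():
    with pytest.raises(ValueError, match="sorted"):
        simulate_root_system(RootParams(), days=(15, 12))


def test_parameter_validation():
    with pytest.raises(ValueError):
        RootParams(lateral_angle_mean_deg=95.0)
    with pytest.raises(ValueError):
        RootParams(primary_rate=-1.0)
    with pytest.raises(ValueError):
        RootParams(diameter_base_cm=0.05, diameter_tip_cm=0.08)
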