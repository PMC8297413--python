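"""The six causal estimators against independent oracles and hand traces."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrsuite import (
    InsufficientInstrumentsError,
    conmix,
    egger,
    estimate_all,
    ivw,
    presso,
    weighted_median,
    weighted_mode,
)
from mrsuite.estimators import _weighted_median_point

from helpers import make_inst, random_inst


# ---------------------------------------------------------------------- IVW

def test_ivw_homogeneous_ratios():
    """Identical ratios give theta = the common ratio, Q = 0, equal SEs."""
    be = np.array([0.1, 0.2, 0.05, 0.15])
    inst = make_inst(be, 0.3 * be)
    est, het = ivw(inst)
    assert est.theta == pytest.approx(0.3)
    assert het.Q == pytest.approx(0.0, abs=1e-18)
    assert est.se == pytest.approx(est.extras["se_fixed"])  # max(1, .) floor binds


def test_ivw_single_instrument_degrades_to_wald_ratio():
    inst = make_inst([0.1], [0.03], [0.01], [0.005])
    est, het = ivw(inst)
    assert est.theta == pytest.approx(0.3)
    assert est.se == pytest.approx(0.05)
    assert het is None


def test_ivw_equals_origin_constrained_wls_oracle(rng):
    """IVW is the WLS slope of outcome on exposure betas through the origin
    with weights 1/se_outcome² (independent statsmodels oracle)."""
    for _ in range(20):
        inst = random_inst(rng, j=5)
        be = np.array([i.beta_exposure for i in inst.instruments])
        bo = np.array([i.beta_outcome for i in inst.instruments])
        se_o = np.array([i.se_outcome for i in inst.instruments])
        oracle = sm.WLS(bo, be[:, None], weights=se_o**-2).fit()
        est, _ = ivw(inst)
        assert est.theta == pytest.approx(float(oracle.params[0]), rel=1e-8)


def test_ivw_order_invariance(rng):
    inst = random_inst(rng, j=8)
    shuffled = inst.subset(list(reversed(inst.variant_ids)))
    assert ivw(inst)[0].theta == pytest.approx(ivw(shuffled)[0].theta, rel=1e-12)


def test_ivw_random_effects_never_below_fixed(rng):
    inst = random_inst(rng, j=10)
    est_r, _ = ivw(inst, model="multiplicative-random")
    est_f, _ = ivw(inst, model="fixed")
    assert est_r.se >= est_f.se
    assert est_r.theta == pytest.approx(est_f.theta)


# ---------------------------------------------------------------------- Egger

def test_egger_exact_linear_data():
    """Data generated as outcome = 0.05 + 0.3·exposure exactly."""
    be = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
    inst = make_inst(be, 0.05 + 0.3 * be)
    est, pleio, het = egger(inst)
    assert est.theta == pytest.approx(0.3, rel=1e-9)
    assert pleio.intercept == pytest.approx(0.05, rel=1e-9)
    assert het.Q == pytest.approx(0.0, abs=1e-16)


def test_egger_matches_statsmodels_wls_oracle(rng):
    for _ in range(20):
        inst = random_inst(rng, j=5)
        be = np.array([i.beta_exposure for i in inst.instruments])
        bo = np.array([i.beta_outcome for i in inst.instruments])
        se_o = np.array([i.se_outcome for i in inst.instruments])
        sign = np.where(be < 0, -1.0, 1.0)
        x, y = be * sign, bo * sign
        oracle = sm.WLS(y, sm.add_constant(x), weights=se_o**-2).fit()
        est, pleio, _ = egger(inst)
        assert est.theta == pytest.approx(float(oracle.params[1]), rel=1e-8)
        assert pleio.intercept == pytest.approx(float(oracle.params[0]), rel=1e-8)
        if oracle.scale > 1.0:  # our SEs apply the max(1, RSS/(J-2)) floor
            assert est.se == pytest.approx(float(oracle.bse[1]), rel=1e-8)


def test_egger_orientation_invariance(rng):
    """Flipping both coefficients' signs of any instrument leaves Egger unchanged."""
    inst = random_inst(rng, j=6)
    flipped = make_inst(
        [-i.beta_exposure for i in inst.instruments],
        [-i.beta_outcome for i in inst.instruments],
        [i.se_exposure for i in inst.instruments],
        [i.se_outcome for i in inst.instruments],
    )
    a, pa, _ = egger(inst)
    b, pb, _ = egger(flipped)
    assert a.theta == pytest.approx(b.theta, rel=1e-12)
    assert pa.intercept == pytest.approx(pb.intercept, rel=1e-12)


def test_egger_with_zero_intercept_equals_ivw(rng):
    """The origin-constrained weighted fit coincides with fixed-effect IVW."""
    inst = random_inst(rng, j=5)
    be = np.array([i.beta_exposure for i in inst.instruments])
    bo = np.array([i.beta_outcome for i in inst.instruments])
    w = np.array([i.se_outcome for i in inst.instruments]) ** -2.0
    slope_origin = float((w * be * bo).sum() / (w * be * be).sum())
    est, _ = ivw(inst, model="fixed")
    assert slope_origin == pytest.approx(est.theta, rel=1e-12)


def test_egger_requires_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        egger(make_inst([0.1, 0.2], [0.03, 0.06]))


# ------------------------------------------------------------ weighted median

def test_weighted_median_unweighted_case():
    inst = make_inst([1.0, 1.0, 1.0], [0.1, 0.2, 0.9])
    est = weighted_median(inst, n_boot=0)
    assert est.theta == pytest.approx(0.2)


def test_weighted_median_dominant_instrument():
    """An instrument with > 50% of weight pins the median to (near) its ratio."""
    # se_ratio = se_out/|be|: weights 100, 1, 1 -> cumulative rule lands inside
    # the dominant instrument's bracket
    inst = make_inst([1.0, 1.0, 1.0], [0.1, 0.5, 0.9],
                     se_outcome=[0.01, 0.1, 0.1])
    est = weighted_median(inst, n_boot=0)
    assert est.theta == pytest.approx(0.1, abs=0.02)


def test_weighted_median_interpolation_hand_trace():
    """Equal weights, ratios (0, 1, 2, 3): mid-cumulative weights are
    (1/8, 3/8, 5/8, 7/8); interpolating 0.5 between 1 and 2 gives 1.5."""
    inst = make_inst([1.0] * 4, [0.0, 1.0, 2.0, 3.0])
    est = weighted_median(inst, n_boot=0)
    assert est.theta == pytest.approx(1.5)


def test_weighted_median_bootstrap_se_reasonable(rng):
    inst = random_inst(rng, j=10)
    est = weighted_median(inst, n_boot=400, seed=5)
    assert est.se is not None and est.se > 0
    assert est.ci_contains(est.theta)


def test_weighted_median_robust_to_minority_invalid(rng):
    """With 30% invalid instruments carrying < 50% of weight, the median stays
    near the true effect while the plain IVW mean is dragged away."""
    theta = 0.1
    n_rep, ests_med, ests_ivw = 60, [], []
    for k in range(n_rep):
        r = np.random.default_rng(1000 + k)
        be = r.uniform(0.08, 0.2, size=20)
        se_o = np.full(20, 0.004)
        alpha = np.zeros(20)
        alpha[:6] = 0.02  # directional pleiotropy on 6 of 20
        bo = theta * be + alpha + r.normal(0, se_o)
        inst = make_inst(be, bo, np.full(20, 0.004), se_o)
        ests_med.append(weighted_median(inst, n_boot=0).theta)
        ests_ivw.append(ivw(inst)[0].theta)
    bias_med = abs(np.mean(ests_med) - theta)
    bias_ivw = abs(np.mean(ests_ivw) - theta)
    assert bias_med < bias_ivw
    assert bias_med < 0.02


# -------------------------------------------------------------- weighted mode

def test_weighted_mode_identical_ratios():
    inst = make_inst([0.1, 0.2, 0.3], [0.05, 0.1, 0.15])
    est = weighted_mode(inst, n_boot=0)
    assert est.theta == pytest.approx(0.5)


def test_weighted_mode_majority_cluster_vs_fine_grid_oracle():
    """Bimodal ratios 0.0 (7 instruments) vs 0.5 (3): the mode tracks the
    majority cluster, matching an independent fine-grid density argmax."""
    ratios = np.array([0.0] * 7 + [0.5] * 3) + np.linspace(-0.01, 0.01, 10)
    inst = make_inst(np.ones(10), ratios)
    est = weighted_mode(inst, n_boot=0)
    # independent oracle: weighted normal-kernel density on a 20001-point grid
    r = ratios
    h = 1.0 * 0.9 * min(np.std(r, ddof=1), np.subtract(*np.percentile(r, [75, 25])) / 1.349) \
        * r.size ** (-0.2)
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 20001)
    dens = np.exp(-0.5 * ((grid[:, None] - r) / h) ** 2).sum(axis=1)
    oracle = grid[np.argmax(dens)]
    assert abs(est.theta - oracle) < 2 * h / 100
    assert abs(est.theta) < 0.1  # majority mode, not the 0.5 cluster


def test_weighted_mode_phi_smoothing_is_continuous(rng):
    inst = random_inst(rng, j=8)
    a = weighted_mode(inst, phi=1.0, n_boot=0).theta
    b = weighted_mode(inst, phi=2.0, n_boot=0).theta
    assert np.isfinite(a) and np.isfinite(b)


# ------------------------------------------------------------------ MR-PRESSO

def _presso_inst(rng, j=20, outlier=False):
    be = rng.uniform(0.08, 0.2, size=j)
    se_o = np.full(j, 0.004)
    bo = 0.1 * be + rng.normal(0, se_o)
    if outlier:
        bo[0] += 10 * se_o[0]
    return make_inst(be, bo, np.full(j, 0.004), se_o)


def test_presso_planted_outlier_recovered(rng):
    inst = _presso_inst(rng, outlier=True)
    res = presso(inst, n_sim=600, seed=2)
    assert "v0" in res.outlier_ids
    assert res.distortion_p is not None
    assert res.corrected_estimate.n_snps == 20 - len(res.outlier_ids)


def test_presso_no_outliers_corrected_equals_raw(rng):
    inst = _presso_inst(rng, outlier=False)
    res = presso(inst, n_sim=600, seed=3)
    if not res.outlier_ids:
        assert res.corrected_estimate is res.raw_estimate
        assert res.distortion_p is None
    assert res.global_rss_p > 0.01  # homogeneous data: global test not extreme


def test_presso_requires_four_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        presso(make_inst([0.1] * 3, [0.02] * 3))


# -------------------------------------------------------- contamination mixture

def test_conmix_valid_instruments_single_segment(rng):
    be = rng.uniform(0.1, 0.2, size=15)
    se_o = np.full(15, 0.002)
    bo = 0.3 * be + rng.normal(0, se_o)
    inst = make_inst(be, bo, np.full(15, 0.004), se_o)
    est = conmix(inst, seed=1)
    assert len(est.ci_segments) == 1
    assert est.ci_contains(0.3)
    assert est.theta == pytest.approx(0.3, abs=0.02)


def test_conmix_two_clusters_give_disjoint_segments():
    """Equally strong instrument clusters at two competing effects leave the
    profile likelihood bimodal, so the confidence set splits into disjoint
    ranges.  (A cluster at exactly zero would instead be absorbed by the
    zero-centred contamination component.)"""
    ratios = np.array([-0.3] * 8 + [0.3] * 8)
    inst = make_inst(np.ones(16), ratios, se_outcome=np.full(16, 0.02))
    est = conmix(inst)
    assert len(est.ci_segments) >= 2
    assert est.extras["n_ci_segments"] == len(est.ci_segments)


def test_conmix_point_estimate_inside_confidence_set(rng):
    for k in range(10):
        inst = random_inst(np.random.default_rng(k), j=8)
        est = conmix(inst)
        assert est.ci_contains(est.theta)


def test_conmix_psi_variation_consistent(rng):
    be = rng.uniform(0.1, 0.2, size=15)
    se_o = np.full(15, 0.002)
    bo = 0.3 * be + rng.normal(0, se_o)
    inst = make_inst(be, bo, np.full(15, 0.004), se_o)
    base = conmix(inst)
    psi0 = base.extras["psi"]
    thetas = [conmix(inst, psi=f * psi0).theta for f in (0.5, 1.0, 2.0)]
    step = base.extras["grid_step"]
    assert max(thetas) - min(thetas) <= 2 * step + 1e-12


def test_conmix_degenerate_point_mass():
    inst = make_inst([1.0, 1.0], [0.3, 0.3], se_outcome=[1e-12, 1e-12])
    est = conmix(inst)
    assert est.theta == pytest.approx(0.3)


# ---------------------------------------------------------------- batch runner

def test_estimate_all_cardinality_and_shared_seed(rng):
    inst = random_inst(rng, j=14)
    panel = estimate_all(inst, seed=9, n_boot=100, n_sim=200)
    assert len(panel) == 6
    assert not panel.failures
    panel2 = estimate_all(inst, seed=9, n_boot=100, n_sim=200)
    for a, b in zip(panel, panel2):
        assert a.theta == b.theta and a.se == b.se  # deterministic given the seed


def test_estimate_all_homogeneous_instruments_all_methods_agree():
    be = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
    inst = make_inst(be, 0.3 * be)
    panel = estimate_all(inst, seed=0, n_boot=50, n_sim=100)
    for est in panel:
        assert est.theta == pytest.approx(0.3, abs=1e-3), est.method


def test_estimate_all_binary_outcome_reports_odds_ratio(rng):
    inst = random_inst(rng, j=10)
    inst.outcome_trait_type = "binary"
    panel = estimate_all(inst, methods=("ivw",), seed=1)
    est = panel.by_method("ivw")
    assert est.extras["odds_ratio"] == pytest.approx(np.exp(est.theta))
    lo, hi = est.extras["odds_ratio_ci"][0]
    assert lo == pytest.approx(np.exp(est.ci_segments[0][0]))
    # null effect maps to OR of exactly 1
    null = make_inst([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], outcome_trait_type="binary")
    p = estimate_all(null, methods=("ivw",))
    assert p.by_method("ivw").extras["odds_ratio"] == pytest.approx(1.0)


def test_estimate_all_continuous_outcome_has_no_or_transform(rng):
    inst = random_inst(rng, j=10)
    panel = estimate_all(inst, methods=("ivw",), seed=1)
    assert "odds_ratio" not in panel.by_method("ivw").extras


def test_estimate_all_captures_per_method_failures():
    inst = make_inst([0.1, 0.2, 0.3], [0.03, 0.06, 0.09])  # too few for presso
    panel = estimate_all(inst, seed=0, n_boot=50)
    assert "presso" in panel.failures
    assert len(panel) == 5


def test_weighted_median_point_is_weight_scale_invariant(rng):
    r = rng.normal(0.2, 0.1, size=9)
    w = rng.uniform(0.5, 2.0, size=9)
    assert _weighted_median_point(r, w) == pytest.approx(
        _weighted_median_point(r, 10.0 * w), rel=1e-12
    )
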