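"""Causal-effect estimators for two-sample Mendelian randomization.

Given a harmonized instrument set with per-variant Wald ratios r_j and
first-order standard errors, six estimators of the causal effect θ are
provided, each robust to a different pattern of instrument invalidity:

============  =============================================================
ivw           inverse-variance weighted mean of the ratios; multiplicative
              random-effects scaling of the SE by default
egger         weighted regression of outcome on exposure coefficients with
              a free intercept; the intercept estimates average directional
              pleiotropy (requires the InSIDE assumption)
weighted_median
              consistent when valid instruments carry > 50% of the weight
weighted_mode kernel-density mode of the ratios; consistent when the
              largest homogeneous cluster of instruments is valid
presso        residual-sum-and-outlier test: simulation-based global
              heterogeneity p, per-variant outlier flags, and an
              outlier-corrected estimate with a distortion test
conmix        contamination-mixture profile likelihood: each ratio is
              modelled as valid N(θ, se_j²) or invalid N(0, se_j² + ψ²);
              the 95% confidence set may be a union of disjoint intervals
============  =============================================================

Heterogeneity among ratio estimates is quantified by Cochran's Q with a
chi-square reference (J − 1 df for IVW, J − 2 for Egger).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .harmonization import InstrumentSet

logger = logging.getLogger("mrsuite")

Z95 = stats.norm.ppf(0.975)
CHI2_95_DF1 = stats.chi2.ppf(0.95, df=1)  # 3.841...

METHODS = ("ivw", "egger", "weighted_median", "weighted_mode", "presso", "conmix")


class InsufficientInstrumentsError(ValueError):
    """A method was given fewer instruments than its minimum."""


@dataclass
class MREstimate:
    """One method's causal estimate.

    ``ci_segments`` is an ordered tuple of disjoint (lo, hi) pairs at the
    95% level — a single segment for most methods, possibly several for the
    contamination mixture.  ``se`` and ``pvalue`` may be None when a method
    reports a confidence set only (or a bootstrap was skipped).
    """

    method: str
    theta: float
    se: float | None
    ci_segments: tuple[tuple[float, float], ...]
    pvalue: float | None
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def ci_contains(self):
        def _in(x: float) -> bool:
            return any(lo <= x <= hi for lo, hi in self.ci_segments)

        return _in

    @property
    def odds_ratio(self) -> float:
        """exp(theta) — meaningful when theta is on the log-odds scale."""
        return math.exp(self.theta)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic with its chi-square p-value."""

    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    """Egger intercept test for average directional pleiotropy."""

    intercept: float
    se_intercept: float
    pvalue: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion test results."""

    global_rss_p: float
    outlier_ids: list[str]
    distortion_p: float | None
    raw_estimate: MREstimate
    corrected_estimate: MREstimate
    per_snp_p: dict[str, float] = field(default_factory=dict)


def _arrays(inst: InstrumentSet) -> tuple[np.ndarray, ...]:
    be = np.array([i.beta_exposure for i in inst.instruments], dtype=float)
    se_e = np.array([i.se_exposure for i in inst.instruments], dtype=float)
    bo = np.array([i.beta_outcome for i in inst.instruments], dtype=float)
    se_o = np.array([i.se_outcome for i in inst.instruments], dtype=float)
    return be, se_e, bo, se_o


def _ratio_arrays(inst: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    r = np.array([i.ratio for i in inst.instruments], dtype=float)
    se_r = np.array([i.se_ratio for i in inst.instruments], dtype=float)
    return r, se_r


def _single_segment(theta: float, se: float, crit: float = Z95) -> tuple[tuple[float, float], ...]:
    return ((theta - crit * se, theta + crit * se),)


def _normal_p(theta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(theta) / se)) if se > 0 else 0.0


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def _ivw_core(r: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """theta, fixed-effect se, Cochran's Q for inverse-variance weights w."""
    sw = w.sum()
    theta = float((w * r).sum() / sw)
    q = float((w * (r - theta) ** 2).sum())
    return theta, float(sw ** -0.5), q


def ivw(
    inst: InstrumentSet, model: str = "multiplicative-random"
) -> tuple[MREstimate, HeterogeneityResult | None]:
    """Inverse-variance weighted estimate of the causal effect.

    Weights are 1/se_ratio² (equivalently beta_exposure²/se_outcome²).
    Under the multiplicative random-effects model the fixed-effect SE is
    inflated by max(1, sqrt(Q / (J − 1))); a single instrument degrades to
    its Wald ratio with no heterogeneity statistic.
    """
    if model not in ("fixed", "multiplicative-random"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = len(inst)
    if j == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    r, se_r = _ratio_arrays(inst)
    if j == 1:
        theta, se = float(r[0]), float(se_r[0])
        est = MREstimate("ivw", theta, se, _single_segment(theta, se), _normal_p(theta, se), 1,
                         extras={"model": "wald-ratio"})
        return est, None

    w = se_r ** -2.0
    theta, se_fixed, q = _ivw_core(r, w)
    scale = max(1.0, math.sqrt(q / (j - 1))) if model == "multiplicative-random" else 1.0
    se = se_fixed * scale
    het = HeterogeneityResult(q, j - 1, float(stats.chi2.sf(q, j - 1)))
    est = MREstimate(
        "ivw", theta, se, _single_segment(theta, se), _normal_p(theta, se), j,
        extras={"model": model, "se_fixed": se_fixed, "Q": q},
    )
    return est, het


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger(
    inst: InstrumentSet,
) -> tuple[MREstimate, PleiotropyResult, HeterogeneityResult]:
    """MR-Egger regression: weighted fit of outcome on exposure coefficients.

    Instruments are oriented so every exposure coefficient is positive (both
    coefficients' signs flip together, which leaves the Wald ratio
    unchanged), then intercept + slope are fitted by weighted least squares
    with weights 1/se_outcome².  SEs are scaled by max(1, sqrt(RSS/(J−2)))
    and p-values use the t reference with J − 2 df.
    """
    j = len(inst)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {j}")
    be, _, bo, se_o = _arrays(inst)
    sign = np.where(be < 0, -1.0, 1.0)
    x = be * sign
    y = bo * sign
    w = se_o ** -2.0

    # closed-form 2-parameter weighted least squares
    sw, sx, sy = w.sum(), (w * x).sum(), (w * y).sum()
    sxx, sxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * sxx - sx * sx
    if det <= 0:
        raise ValueError("degenerate design: exposure coefficients are collinear")
    intercept = (sxx * sy - sx * sxy) / det
    slope = (sw * sxy - sx * sy) / det
    resid = y - intercept - slope * x
    rss = float((w * resid ** 2).sum())
    sigma2 = max(1.0, rss / (j - 2))
    se_intercept = math.sqrt(sigma2 * sxx / det)
    se_slope = math.sqrt(sigma2 * sw / det)

    tdist = stats.t(df=j - 2)
    p_slope = float(2.0 * tdist.sf(abs(slope) / se_slope))
    p_intercept = float(2.0 * tdist.sf(abs(intercept) / se_intercept))
    tcrit = float(tdist.ppf(0.975))

    het = HeterogeneityResult(rss, j - 2, float(stats.chi2.sf(rss, j - 2)))
    est = MREstimate(
        "egger", float(slope), se_slope,
        _single_segment(float(slope), se_slope, tcrit), p_slope, j,
        extras={"intercept": float(intercept), "se_intercept": se_intercept,
                "Q": rss, "df": j - 2},
    )
    return est, PleiotropyResult(float(intercept), se_intercept, p_intercept), het


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="stable")
    rs, ws = r[order], w[order]
    ws = ws / ws.sum()
    # mid-cumulative weights; interpolate the 50% point
    cum = np.cumsum(ws) - ws / 2.0
    if cum[0] >= 0.5:
        return float(rs[0])
    if cum[-1] <= 0.5:
        return float(rs[-1])
    return float(np.interp(0.5, cum, rs))


def weighted_median(
    inst: InstrumentSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted median of the Wald ratios.

    The estimate is the ratio at cumulative inverse-variance weight 0.5
    (linear interpolation between bracketing ratios); its SE comes from a
    parametric bootstrap that redraws both coefficients from normals with
    their reported SEs.  ``n_boot=0`` skips the bootstrap (point estimate
    only, ``se`` and ``pvalue`` are None).
    """
    j = len(inst)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >= 3 instruments, got {j}")
    r, se_r = _ratio_arrays(inst)
    w = se_r ** -2.0
    theta = _weighted_median_point(r, w)
    if n_boot == 0:
        return MREstimate("weighted_median", theta, None, (), None, j)
    se = _bootstrap_se(inst, _weighted_median_point, n_boot, seed)
    return MREstimate(
        "weighted_median", theta, se, _single_segment(theta, se), _normal_p(theta, se), j
    )


def _bootstrap_se(inst: InstrumentSet, point_fn, n_boot: int, seed: int | None) -> float:
    """Parametric bootstrap SD of a ratio-based point estimator."""
    rng = np.random.default_rng(seed)
    be, se_e, bo, se_o = _arrays(inst)
    be_b = rng.normal(be, se_e, size=(n_boot, be.size))
    bo_b = rng.normal(bo, se_o, size=(n_boot, bo.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_b = bo_b / be_b
        w_b = (be_b / se_o) ** 2
    ests = np.empty(n_boot)
    for k in range(n_boot):
        ests[k] = point_fn(r_b[k], w_b[k])
    return float(np.std(ests, ddof=1))


# ---------------------------------------------------------------------------
# Weighted mode
# ---------------------------------------------------------------------------

def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    sd = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(r, [75, 25])))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * s * r.size ** (-1.0 / 5.0)


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float, refine: bool = False) -> float:
    h = _mode_bandwidth(r, phi)
    if h == 0.0:
        return float(r[0])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    wn = w / w.sum()
    dens = (wn * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    k = int(np.argmax(dens))
    if not refine:
        return float(grid[k])
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]

    def neg_density(x: float) -> float:
        return -float((wn * np.exp(-0.5 * ((x - r) / h) ** 2)).sum())

    res = optimize.minimize_scalar(neg_density, bounds=(lo, hi), method="bounded")
    return float(res.x)


def weighted_mode(
    inst: InstrumentSet, phi: float = 1.0, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Mode of the kernel-smoothed weighted density of the Wald ratios.

    Bandwidth h = phi × 0.9 × min(SD, IQR/1.349) × J^(−1/5) (a modified
    Silverman rule); the density, weighted by normalized inverse-variance
    ratio weights, is evaluated on a 512-point grid spanning the ratios
    ± 3h and the grid argmax is refined by bounded golden-section search.
    When all ratios coincide the bandwidth degenerates and the common ratio
    is returned.  SE via the same parametric bootstrap as the weighted
    median (grid argmax only, no refinement, within the bootstrap).
    """
    j = len(inst)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted mode requires >= 3 instruments, got {j}")
    r, se_r = _ratio_arrays(inst)
    w = se_r ** -2.0
    theta = _mode_point(r, w, phi, refine=True)
    if n_boot == 0:
        return MREstimate("weighted_mode", theta, None, (), None, j, extras={"phi": phi})
    se = _bootstrap_se(inst, lambda rr, ww: _mode_point(rr, ww, phi), n_boot, seed)
    return MREstimate(
        "weighted_mode", theta, se, _single_segment(theta, se), _normal_p(theta, se), j,
        extras={"phi": phi, "bandwidth": _mode_bandwidth(r, phi)},
    )


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_ivw_theta(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, one per instrument."""
    swr, sw = (w * r).sum(), w.sum()
    return (swr - w * r) / (sw - w)


def presso(
    inst: InstrumentSet,
    n_sim: int = 1000,
    outlier_p: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier analysis.

    (1) Global test: the observed residual sum of squares
    RSS = Σ_j w_j (r_j − θ_(−j))², with θ_(−j) the leave-one-out IVW
    estimate, is compared with ``n_sim`` parametric simulations in which
    each outcome coefficient is redrawn from N(θ_(−j)·beta_exp_j, se_out_j);
    the p-value is the +1-smoothed exceedance probability.  (2) Outlier
    test: each variant's observed weighted squared residual is referred to
    its own simulated distribution, Bonferroni-adjusted across J; variants
    below ``outlier_p`` are flagged.  (3) Distortion test: the shift between
    the raw and outlier-corrected IVW estimates is referred to a null built
    by removing random subsets of the same size.
    """
    j = len(inst)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 instruments, got {j}")
    rng = np.random.default_rng(seed)
    be, _, bo, se_o = _arrays(inst)
    ids = inst.variant_ids
    r, se_r = _ratio_arrays(inst)
    w = se_r ** -2.0

    theta_loo = _loo_ivw_theta(r, w)
    d_obs = w * (r - theta_loo) ** 2
    rss_obs = float(d_obs.sum())

    # parametric null: redraw outcome betas around the leave-one-out fit
    bo_sim = rng.normal(theta_loo * be, se_o, size=(n_sim, j))
    r_sim = bo_sim / be
    swr = (w * r_sim).sum(axis=1, keepdims=True)
    sw = w.sum()
    theta_loo_sim = (swr - w * r_sim) / (sw - w)
    d_sim = w * (r_sim - theta_loo_sim) ** 2
    rss_sim = d_sim.sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))

    per_snp_raw = (1 + (d_sim >= d_obs).sum(axis=0)) / (n_sim + 1)
    per_snp_adj = np.minimum(per_snp_raw * j, 1.0)
    outliers = [ids[k] for k in range(j) if per_snp_adj[k] < outlier_p]

    raw_est, _ = ivw(inst)
    raw_est.method = "presso"
    raw_est.extras["role"] = "raw"

    if outliers:
        kept = inst.subset([v for v in ids if v not in outliers])
        corrected, _ = ivw(kept)
        corrected.method = "presso"
        corrected.extras["role"] = "outlier-corrected"
        corrected.extras["outliers_removed"] = outliers

        # distortion null: remove random subsets of the same size
        n_out = len(outliers)
        d_shift = np.empty(n_sim)
        idx = np.arange(j)
        for b in range(n_sim):
            drop = rng.choice(idx, size=n_out, replace=False)
            keep = np.setdiff1d(idx, drop, assume_unique=True)
            th, _, _ = _ivw_core(r[keep], w[keep])
            d_shift[b] = raw_est.theta - th
        obs_shift = raw_est.theta - corrected.theta
        distortion_p = float((1 + (np.abs(d_shift) >= abs(obs_shift)).sum()) / (n_sim + 1))
    else:
        corrected = raw_est
        distortion_p = None

    return PressoResult(
        global_rss_p=global_p,
        outlier_ids=outliers,
        distortion_p=distortion_p,
        raw_estimate=raw_est,
        corrected_estimate=corrected,
        per_snp_p={ids[k]: float(per_snp_adj[k]) for k in range(j)},
    )


# ---------------------------------------------------------------------------
# Contamination mixture
# ---------------------------------------------------------------------------

def conmix(
    inst: InstrumentSet,
    psi: float | None = None,
    grid_points: int = 2001,
    seed: int | None = None,
) -> MREstimate:
    """Contamination-mixture profile-likelihood estimate.

    Over a grid of candidate θ spanning [min r − 2·max se, max r + 2·max se],
    each instrument contributes the larger of a valid log-likelihood
    N(r_j; θ, se_j²) and an invalid one N(r_j; 0, se_j² + ψ²); the profile
    log-likelihood is their sum.  θ̂ is the grid argmax and the 95%
    confidence set is every grid value within half the chi-square(1) 95%
    quantile of the maximum — reported as maximal disjoint segments, which
    may number more than one when the ratios cluster around competing
    effects.  ψ defaults to 1.5 × SD of the ratios.  The p-value is the
    chi-square(1) likelihood-ratio test of θ = 0.
    """
    j = len(inst)
    if j < 2:
        raise InsufficientInstrumentsError(f"contamination mixture requires >= 2 instruments, got {j}")
    r, se_r = _ratio_arrays(inst)
    if psi is None:
        psi = 1.5 * float(np.std(r, ddof=1))
    spread = 2.0 * float(se_r.max())
    lo, hi = float(r.min()) - spread, float(r.max()) + spread
    if lo == hi:  # all ratios equal with vanishing spread: point mass
        theta = float(r[0])
        return MREstimate("conmix", theta, None, ((theta, theta),), None, j,
                          extras={"psi": psi, "degenerate": True})
    grid = np.linspace(lo, hi, grid_points)

    inv_var = se_r ** 2 + psi ** 2
    ll_invalid = -0.5 * (r ** 2 / inv_var) - 0.5 * np.log(2 * np.pi * inv_var)
    dev = (grid[:, None] - r[None, :]) / se_r[None, :]
    ll_valid = -0.5 * dev ** 2 - 0.5 * np.log(2 * np.pi * se_r ** 2)[None, :]
    profile = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)

    k = int(np.argmax(profile))
    theta = float(grid[k])
    ll_max = float(profile[k])
    in_set = 2.0 * (ll_max - profile) < CHI2_95_DF1

    segments: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(in_set):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        segments.append((float(grid[start]), float(grid[-1])))

    # likelihood-ratio p-value against theta = 0
    ll_valid0 = -0.5 * (r / se_r) ** 2 - 0.5 * np.log(2 * np.pi * se_r ** 2)
    ll0 = float(np.maximum(ll_valid0, ll_invalid).sum())
    pvalue = float(stats.chi2.sf(max(0.0, 2.0 * (ll_max - ll0)), df=1))

    return MREstimate(
        "conmix", theta, None, tuple(segments), pvalue, j,
        extras={"psi": psi, "grid_step": float(grid[1] - grid[0]),
                "n_ci_segments": len(segments)},
    )


# ---------------------------------------------------------------------------
# Batch runner
# ---------------------------------------------------------------------------

class MethodPanel(Sequence):
    """Estimates from a batch run; per-method failures are captured, not fatal."""

    def __init__(self) -> None:
        self.estimates: list[MREstimate] = []
        self.failures: dict[str, str] = {}
        self.heterogeneity: dict[str, HeterogeneityResult] = {}
        self.pleiotropy: PleiotropyResult | None = None
        self.presso_detail: PressoResult | None = None

    def __len__(self) -> int:
        return len(self.estimates)

    def __getitem__(self, i):
        return self.estimates[i]

    def by_method(self, method: str) -> MREstimate | None:
        for e in self.estimates:
            if e.method == method:
                return e
        return None


def estimate_all(
    inst: InstrumentSet,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    psi: float | None = None,
    n_boot: int = 1000,
    n_sim: int = 1000,
    phi: float = 1.0,
) -> MethodPanel:
    """Run a panel of estimators with a shared seed stream.

    For binary outcomes (log-odds effect scale) each estimate's extras carry
    the odds-ratio transform exp(θ) with exp-transformed CI endpoints.
    Individual method failures are recorded in ``panel.failures`` and do not
    abort the batch.
    """
    panel = MethodPanel()
    streams = {m: s for m, s in zip(METHODS, np.random.SeedSequence(seed).spawn(len(METHODS)))}

    def child_seed(method: str) -> int:
        return int(streams[method].generate_state(1)[0] % (2**31))

    for method in methods:
        try:
            if method == "ivw":
                est, het = ivw(inst)
                if het is not None:
                    panel.heterogeneity["ivw"] = het
            elif method == "egger":
                est, pleio, het = egger(inst)
                panel.pleiotropy = pleio
                panel.heterogeneity["egger"] = het
            elif method == "weighted_median":
                est = weighted_median(inst, n_boot=n_boot, seed=child_seed(method))
            elif method == "weighted_mode":
                est = weighted_mode(inst, phi=phi, n_boot=n_boot, seed=child_seed(method))
            elif method == "presso":
                detail = presso(inst, n_sim=n_sim, seed=child_seed(method))
                panel.presso_detail = detail
                est = detail.corrected_estimate
                est.extras["global_rss_p"] = detail.global_rss_p
                est.extras["n_outliers"] = len(detail.outlier_ids)
            elif method == "conmix":
                est = conmix(inst, psi=psi, seed=child_seed(method))
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as exc:  # noqa: BLE001 - contract: capture, don't abort
            logger.warning("method %s failed: %s", method, exc)
            panel.failures[method] = str(exc)
            continue

        est.extras.setdefault("exposure", inst.exposure_name)
        est.extras.setdefault("outcome", inst.outcome_name)
        if inst.outcome_trait_type == "binary":
            est.extras["odds_ratio"] = math.exp(est.theta)
            est.extras["odds_ratio_ci"] = tuple(
                (math.exp(lo), math.exp(hi)) for lo, hi in est.ci_segments
            )
        panel.estimates.append(est)
    return panel
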