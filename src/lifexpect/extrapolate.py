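"""Logit relative-survival rolling extrapolation and life-expectancy estimation.

The estimator assumes patients survive systematically worse than their
age/sex/calendar-year matched referents. Each observed month the survival
ratio r(t) = S_p(t)/S_r(t) is logit-transformed, W(t) = log(r/(1-r)).
A restricted cubic spline (linear beyond its boundary knots) is regressed
on time over a rolling window of recent months and its linear tail predicts
W one month ahead; the predicted patient survival is expit(W)*S_r at the
next month. The prediction is appended, the oldest window month dropped,
and the step repeated until survival approaches zero. Life expectancy (LE)
is the area under the full patient curve; loss of LE is the referent LE
minus the patient LE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .errors import InsufficientFollowupError, NonEstimableError, ValidationError
from .lifetable import ReferentCurve
from .survival import MonthlySurvivalCurve


@dataclass
class ExtrapolationConfig:
    """Tunables of the rolling extrapolation.

    window: rolling fit window length in months; None (default) sizes the
    window as ``window_fraction`` of the valid observed months, so the fit
    pools most of the follow-up while the earliest months can still be
    rolled out (min_window is the least number of valid observed months
    required to start).
    knot_quantiles: restricted-cubic-spline knot placement as quantiles of
    the window's time points.
    epsilon: survival level treated as "has reached zero".
    auc_ratio_threshold / max_ratio_violations / estimability_z: the
    estimability decision — a stratum is refused unless the observed-window
    area under S_p is below ``auc_ratio_threshold`` times the area under
    S_r AND below it by at least ``estimability_z`` standard errors of the
    ratio (one-sided test that patients really are worse, so Kaplan-Meier
    noise alone cannot fake an excess-mortality signal); it is also refused
    when more than ``max_ratio_violations`` of observed months have
    ratio >= 1.
    min_at_risk: observed months whose Kaplan-Meier risk set has fewer
    subjects are dropped before anchoring the fit window — with staggered
    entry the far tail of the KM curve goes artificially flat once only a
    handful of the earliest-diagnosed patients remain, and a fit anchored
    there tilts the extrapolated logit ratio upward.
    """
    window: int | None = None
    window_fraction: float = 0.75
    min_window: int = 12
    knot_quantiles: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95)
    epsilon: float = 1e-4
    auc_ratio_threshold: float = 0.98
    max_ratio_violations: float = 0.20
    estimability_z: float = 1.645
    min_at_risk: int = 25


@dataclass
class EstimabilityDiagnostic:
    estimable: bool
    auc_patient: float
    auc_referent: float
    auc_ratio: float
    frac_months_ratio_ge_1: float
    reason: str = ""


@dataclass
class RelativeSurvivalSeries:
    """W(t) = logit(S_p/S_r) on observed months t >= 1 with a validity mask
    (months where the ratio falls outside (0,1) are masked, not imputed)."""
    t: np.ndarray
    w: np.ndarray
    valid: np.ndarray

    @property
    def t_valid(self) -> np.ndarray:
        return self.t[self.valid]

    @property
    def w_valid(self) -> np.ndarray:
        return self.w[self.valid]


@dataclass
class ExtrapolationResult:
    s_patient: np.ndarray      # full curve 0..horizon (observed + extrapolated)
    s_referent: np.ndarray
    le: float                  # years
    le_referent: float
    loss_le: float
    estimable: bool
    horizon_months: int
    truncated: bool = False
    t_obs: int = 0
    predicted_w: np.ndarray = field(default_factory=lambda: np.empty(0))


def truncate_unreliable_tail(curve: MonthlySurvivalCurve, min_at_risk: int) -> np.ndarray:
    """Observed survival truncated to the last month whose risk set still
    holds at least ``min_at_risk`` subjects (whole curve if none does)."""
    ok = np.nonzero(curve.n_at_risk >= min_at_risk)[0]
    if ok.size == 0:
        return curve.s
    return curve.s[: ok[-1] + 1]


def life_expectancy(s: np.ndarray) -> float:
    """Area under a monthly survival curve by the trapezoidal rule, in years."""
    return float(np.trapezoid(np.asarray(s, float))) / 12.0


def _observed_aucs(s_p: np.ndarray, s_r: np.ndarray) -> tuple[float, float, np.ndarray]:
    t_obs = len(s_p) - 1
    if len(s_r) - 1 < t_obs:
        s_r = np.concatenate([s_r, np.zeros(t_obs - (len(s_r) - 1))])
    s_r_obs = s_r[: t_obs + 1]
    return float(np.trapezoid(s_p)), float(np.trapezoid(s_r_obs)), s_r_obs


def km_auc_variance(curve: MonthlySurvivalCurve, t_max: int | None = None) -> float:
    """Sampling variance of the area under the product-limit curve up to
    ``t_max`` (Greenwood-type restricted-mean variance on the month grid):
    Var = sum_m A(m)^2 d_m / (n_m (n_m - d_m)), A(m) the area beyond m."""
    s = curve.s if t_max is None else curve.s[: t_max + 1]
    T = len(s) - 1
    # A(m): trapezoid area of S over [m, T]
    seg = 0.5 * (s[:-1] + s[1:])
    area_beyond = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    d = curve.n_events[: T + 1].astype(float)
    n = curve.n_at_risk[: T + 1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where((n > d) & (d > 0), d / (n * (n - d)), 0.0)
    return float(np.sum(area_beyond ** 2 * term))


def check_estimability(s_p: np.ndarray, s_r: np.ndarray,
                       config: ExtrapolationConfig | None = None,
                       auc_ratio_se: float | None = None) -> EstimabilityDiagnostic:
    """Decide whether patient survival is materially worse than the referents.

    Operationalises "similar or even better than the reference group": the
    stratum is estimable only when the observed-window AUC ratio is below
    the material threshold and, when a standard error for the ratio is
    supplied, significantly below 1 (one-sided z test); it is also refused
    when ratio >= 1 in too many observed months.
    """
    cfg = config or ExtrapolationConfig()
    auc_p, auc_r, s_r_obs = _observed_aucs(np.asarray(s_p, float), np.asarray(s_r, float))
    ratio = auc_p / auc_r if auc_r > 0 else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        monthly = np.where(s_r_obs[1:] > 0, s_p[1:] / s_r_obs[1:], np.inf)
    frac_ge_1 = float(np.mean(monthly >= 1.0)) if monthly.size else 1.0
    threshold = cfg.auc_ratio_threshold
    if auc_ratio_se is not None:
        threshold = min(threshold, 1.0 - cfg.estimability_z * auc_ratio_se)
    if ratio >= threshold:
        return EstimabilityDiagnostic(False, auc_p, auc_r, ratio, frac_ge_1,
                                      f"AUC ratio {ratio:.4f} >= {threshold:.4f}")
    if frac_ge_1 > cfg.max_ratio_violations:
        return EstimabilityDiagnostic(False, auc_p, auc_r, ratio, frac_ge_1,
                                      f"{frac_ge_1:.0%} of months have ratio >= 1")
    return EstimabilityDiagnostic(True, auc_p, auc_r, ratio, frac_ge_1)


def logit_relative_survival(s_p: np.ndarray, s_r: np.ndarray,
                            config: ExtrapolationConfig | None = None) -> RelativeSurvivalSeries:
    """Monthly logit of the patient/referent survival ratio over months
    1..T_obs. Months where the ratio leaves (0,1) are masked."""
    cfg = config or ExtrapolationConfig()
    s_p = np.asarray(s_p, float)
    _, _, s_r_obs = _observed_aucs(s_p, np.asarray(s_r, float))
    t = np.arange(1, len(s_p))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(s_r_obs[1:] > 0, s_p[1:] / s_r_obs[1:], np.nan)
    valid = np.isfinite(r) & (r > 0) & (r < 1)
    w = np.full(t.shape, np.nan)
    w[valid] = logit(r[valid])
    if valid.sum() < cfg.min_window:
        raise InsufficientFollowupError(
            f"only {int(valid.sum())} valid months; need >= {cfg.min_window}")
    return RelativeSurvivalSeries(t=t, w=w, valid=valid)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's truncated-power form):
    columns [x, b_1(x), ..., b_{K-2}(x)], linear beyond the boundary knots."""
    x = np.asarray(x, float)
    k = np.asarray(knots, float)
    K = len(k)
    if K < 3:
        raise ValidationError("restricted cubic spline needs >= 3 knots")
    denom = (k[-1] - k[0]) ** 2

    def tp(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(K - 2):
        cols.append((tp(x - k[j])
                     - tp(x - k[K - 2]) * (k[-1] - k[j]) / (k[-1] - k[K - 2])
                     + tp(x - k[-1]) * (k[K - 2] - k[j]) / (k[-1] - k[K - 2])) / denom)
    return np.column_stack(cols)


def _window_knots(t_window: np.ndarray, quantiles) -> np.ndarray:
    knots = np.quantile(t_window, np.asarray(quantiles, float))
    return np.unique(knots)


def fit_rcs_one_step(t_window: np.ndarray, w_window: np.ndarray,
                     config: ExtrapolationConfig | None = None,
                     t_predict: float | None = None) -> float:
    """Fit W ~ RCS(t) over a window and return the linear-tail prediction at
    ``t_predict`` (default: one month past the window's last point)."""
    cfg = config or ExtrapolationConfig()
    t_window = np.asarray(t_window, float)
    w_window = np.asarray(w_window, float)
    if t_window.size < 3 or np.ptp(t_window) == 0:
        raise ValidationError("degenerate fit window (too few or constant time points)")
    if t_predict is None:
        t_predict = t_window[-1] + 1
    knots = _window_knots(t_window, cfg.knot_quantiles)
    if len(knots) < 3:  # very short windows collapse to a line
        X = np.column_stack([np.ones_like(t_window), t_window])
        beta, *_ = np.linalg.lstsq(X, w_window, rcond=None)
        return float(beta[0] + beta[1] * t_predict)
    X = np.column_stack([np.ones_like(t_window), rcs_basis(t_window, knots)])
    beta, *_ = np.linalg.lstsq(X, w_window, rcond=None)
    x_pred = np.concatenate([[1.0], rcs_basis(np.array([t_predict]), knots)[0]])
    return float(x_pred @ beta)


def _hat_vector(window: int, quantiles) -> np.ndarray:
    """One-step-ahead prediction as a fixed linear functional of the W values
    of a window of consecutive months (translation-equivariant, so the hat
    vector depends only on the window length)."""
    u = np.arange(window, dtype=float)
    knots = _window_knots(u, quantiles)
    X = np.column_stack([np.ones(window), rcs_basis(u, knots)])
    x_pred = np.concatenate([[1.0], rcs_basis(np.array([float(window)]), knots)[0]])
    return x_pred @ np.linalg.pinv(X)


def rolling_extrapolate(observed: MonthlySurvivalCurve | np.ndarray,
                        referent: ReferentCurve | np.ndarray,
                        config: ExtrapolationConfig | None = None,
                        horizon_months: int | None = None,
                        check: bool = True) -> ExtrapolationResult:
    """Extrapolate observed patient survival to lifetime and compute LE and
    loss of LE.

    Each step predicts W one month ahead from the rolling window, converts
    it to survival via S_p(t+1) = expit(W)*S_r(t+1), treats the prediction
    as data, drops the window's oldest month and repeats until survival
    falls to epsilon, the referent curve is exhausted, or the horizon cap is
    reached (the last case flags the LE as a truncated lower bound).
    """
    cfg = config or ExtrapolationConfig()
    if isinstance(observed, MonthlySurvivalCurve):
        s_p_obs = truncate_unreliable_tail(observed, cfg.min_at_risk)
    else:
        s_p_obs = np.asarray(observed, float)
    s_r = referent.s if isinstance(referent, ReferentCurve) else np.asarray(referent, float)
    t_obs = len(s_p_obs) - 1
    if horizon_months is None:
        horizon_months = len(s_r) - 1
    horizon_months = int(max(horizon_months, t_obs))
    # referent padded with zeros beyond its support (it has reached ~zero there)
    if len(s_r) - 1 < horizon_months:
        s_r = np.concatenate([s_r, np.zeros(horizon_months - (len(s_r) - 1))])

    if check:
        diag = check_estimability(s_p_obs, s_r, cfg)
        if not diag.estimable:
            raise NonEstimableError(diag.reason)

    series = logit_relative_survival(s_p_obs, s_r, cfg)
    n_valid = len(series.t_valid)
    window = cfg.window if cfg.window is not None else max(
        cfg.min_window, int(round(cfg.window_fraction * n_valid)))
    window = min(window, n_valid)
    tw = list(series.t_valid[-window:].astype(float))
    ww = list(series.w_valid[-window:])

    hat = _hat_vector(window, cfg.knot_quantiles)
    s_ext: list[float] = []
    w_pred_log: list[float] = []
    s_prev = float(s_p_obs[-1])
    truncated = False
    t = t_obs
    while s_prev > cfg.epsilon:
        if t >= horizon_months:
            truncated = True
            break
        t += 1
        consecutive = (len(tw) == window
                       and tw[-1] == t - 1
                       and tw[0] == t - window)
        if consecutive:
            w_hat = float(hat @ np.asarray(ww))
        else:
            w_hat = fit_rcs_one_step(np.asarray(tw), np.asarray(ww), cfg, t_predict=t)
        s_r_t = s_r[t] if t < len(s_r) else 0.0
        s_next = expit(w_hat) * s_r_t
        w_pred_log.append(w_hat)
        s_ext.append(s_next)
        tw.append(float(t))
        ww.append(w_hat)
        if len(tw) > window:
            tw.pop(0)
            ww.pop(0)
        s_prev = s_next
        if s_r_t <= 0.0:
            s_prev = 0.0
            s_ext[-1] = 0.0
            break

    s_full = np.concatenate([s_p_obs, np.asarray(s_ext)])
    s_full = np.minimum.accumulate(np.clip(s_full, 0.0, 1.0))
    le_p = life_expectancy(s_full)
    le_r = life_expectancy(s_r)
    return ExtrapolationResult(
        s_patient=s_full, s_referent=s_r, le=le_p, le_referent=le_r,
        loss_le=le_r - le_p, estimable=True, horizon_months=horizon_months,
        truncated=truncated, t_obs=t_obs,
        predicted_w=np.asarray(w_pred_log))
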