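"""Fitting the cohort survival model to quadrat census data.

Workflow
--------
Each quadrat census interval yields one observed survival fraction
``S = N_end / N_start``.  Because field censuses happen at irregular
calendar intervals while the model works in equal base steps, survival is
first standardized to a common 30-day step by geometric (per-day
compounding) rescaling, ``S_30 = S ** (30 / T_days)``; model predictions
are rescaled back with the exact inverse.  Each survival functional form
is then linearized —

* exponential:  ``ln S = ln(alpha) - beta * X``
* logistic:     ``ln(1/S - 1) = ln(alpha') + beta * X``
* hyperbolic:   ``1/S = 1/alpha + (beta/alpha) * X``

— and fitted by ordinary least squares against a resource-use descriptor
``X``: density alone, basal-area cover ``B*N`` or operculum-area cover
``O*N``.  Goodness of fit is the adjusted R² on the transformed scale
(the scale the regression is performed on); an untransformed
survival-scale R² is also reported for transparency.

An extended model lets the resource-independent survival ``alpha`` vary
by census period and adds the cover of dead shells as a second mortality
term; the four on/off combinations of those two extensions form a
candidate set compared by Gaussian-OLS AIC.
"""

from __future__ import annotations

import enum
import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import SurvivalForm

__all__ = [
    "Descriptor",
    "QuadratObservation",
    "ExtendedModelSpec",
    "IntervalSurvival",
    "DesignMatrix",
    "BackTransformed",
    "FitResult",
    "ResidualDiagnostics",
    "CLIP_EPS",
    "BASE_DAYS",
    "interval_survival",
    "standardize_survival",
    "rescale_prediction",
    "linearize",
    "build_design",
    "fit_form",
    "back_transform_params",
    "adjusted_r2",
    "residual_trend",
    "fit_extended",
    "aic",
    "select_by_aic",
    "fit_table",
]

#: Clipping constant applied to observed survival before transforming.
CLIP_EPS = 1e-6

#: Base interval (days) that all fitting is standardized to.
BASE_DAYS = 30.0


class Descriptor(str, enum.Enum):
    """Resource-use descriptor used as the regression predictor."""

    DENSITY = "density"          # X = N_t
    BASAL_COVER = "basal_cover"  # X = B_t * N_t
    OPERC_COVER = "operc_cover"  # X = O_t * N_t


@dataclass(frozen=True)
class QuadratObservation:
    """One census interval for one quadrat.

    Densities are individuals per quadrat; trait areas are mm² per
    individual; dead cover is mm² per quadrat.  Trait fields may be NaN when
    a descriptor that needs them is not being fitted.
    """

    shore: str
    quadrat: str
    period: str
    T_days: float
    N_start: float
    N_end: float
    operc_area: float = math.nan
    basal_area: float = math.nan
    dead_cover: float = 0.0

    def __post_init__(self) -> None:
        if self.T_days <= 0:
            raise ValueError(f"T_days must be > 0, got {self.T_days}")
        if self.N_start < 0 or self.N_end < 0:
            raise ValueError("densities must be >= 0")


@dataclass(frozen=True)
class ExtendedModelSpec:
    """Switches defining one member of the extended-model candidate set."""

    alpha_by_period: bool
    include_dead_cover: bool

    def label(self) -> str:
        a = "alpha(period)" if self.alpha_by_period else "alpha(const)"
        d = "+dead" if self.include_dead_cover else ""
        return a + d


@dataclass(frozen=True)
class IntervalSurvival:
    """Observed interval survival with clipping bookkeeping."""

    raw: float
    value: float
    clipped: bool
    excluded: bool
    reason: str | None = None


def interval_survival(N_start: float, N_end: float) -> IntervalSurvival:
    """Observed survival fraction ``S = N_end / N_start`` over one interval.

    The raw ratio is kept alongside a value clipped into
    ``[CLIP_EPS, 1 - CLIP_EPS]`` so the log / logit / reciprocal transforms
    stay finite.  A zero starting density cannot define survival: the
    observation is flagged excluded rather than raising, so a balanced
    design can be filtered, not aborted.  ``S > 1`` (a recount error in an
    intended closed cohort) warns and clips to keep the design balanced.
    """
    if N_start < 0 or N_end < 0:
        raise ValueError("densities must be >= 0")
    if N_start == 0:
        return IntervalSurvival(
            raw=math.nan, value=math.nan, clipped=False, excluded=True,
            reason="zero initial density",
        )
    raw = N_end / N_start
    if raw > 1.0:
        warnings.warn(
            f"interval survival {raw:.4g} > 1 (recount error in a closed "
            f"cohort); clipping",
            stacklevel=2,
        )
    value = min(max(raw, CLIP_EPS), 1.0 - CLIP_EPS)
    return IntervalSurvival(
        raw=raw, value=value, clipped=(value != raw), excluded=False
    )


def standardize_survival(S: float, T_days: float, base: float = BASE_DAYS) -> float:
    """Convert an interval survival to the common base interval.

    Survival compounds multiplicatively over sub-intervals, so the
    standardization is geometric: ``S_base = S ** (base / T_days)``.
    """
    if not (0.0 < S <= 1.0):
        raise ValueError(f"S must be in (0, 1], got {S}")
    if T_days <= 0:
        raise ValueError(f"T_days must be > 0, got {T_days}")
    return S ** (base / T_days)


def rescale_prediction(lambda_base: float, T_days: float, base: float = BASE_DAYS) -> float:
    """Rescale a base-interval survival prediction to an observation interval.

    Exact inverse of :func:`standardize_survival`:
    ``lambda_T = lambda_base ** (T_days / base)``.
    """
    if not (0.0 < lambda_base <= 1.0):
        raise ValueError(f"lambda_base must be in (0, 1], got {lambda_base}")
    if T_days <= 0:
        raise ValueError(f"T_days must be > 0, got {T_days}")
    return lambda_base ** (T_days / base)


def linearize(form: SurvivalForm, S: float | np.ndarray) -> float | np.ndarray:
    """Transform survival onto the scale where each form is linear in X."""
    S_arr = np.asarray(S, dtype=float)
    if np.any((S_arr <= 0.0) | (S_arr >= 1.0)):
        raise ValueError("S must lie strictly inside (0, 1) after clipping")
    form = SurvivalForm(form)
    if form is SurvivalForm.EXPONENTIAL:
        out = np.log(S_arr)
    elif form is SurvivalForm.LOGISTIC:
        out = np.log(1.0 / S_arr - 1.0)
    else:
        out = 1.0 / S_arr
    if np.isscalar(S) or S_arr.ndim == 0:
        return float(out)
    return out


def _descriptor_x(obs: QuadratObservation, descriptor: Descriptor) -> float:
    if descriptor is Descriptor.DENSITY:
        return obs.N_start
    if descriptor is Descriptor.BASAL_COVER:
        return obs.basal_area * obs.N_start
    return obs.operc_area * obs.N_start


@dataclass
class DesignMatrix:
    """Paired predictor / transformed-response samples ready for OLS."""

    X: np.ndarray
    y: np.ndarray
    s_raw: np.ndarray
    s30: np.ndarray
    T_days: np.ndarray
    dead_cover: np.ndarray
    shore: list[str]
    period: list[str]
    quadrat: list[str]
    n_excluded: int
    n_clipped: int

    @property
    def n(self) -> int:
        return self.X.size

    def data_key(self) -> str:
        """Fingerprint of the underlying observation set (form-independent)."""
        h = hashlib.sha256()
        h.update(np.round(self.s30, 12).tobytes())
        h.update(np.round(self.X, 12).tobytes())
        return h.hexdigest()


def build_design(
    observations: Iterable[QuadratObservation],
    descriptor: Descriptor,
    form: SurvivalForm,
    base: float = BASE_DAYS,
) -> DesignMatrix:
    """Assemble (X, transformed response) pairs from census observations.

    One record per quadrat × interval.  Observations with zero starting
    density are excluded (counted); survivals at the clip boundary are
    counted.  Missing trait values under a trait descriptor are an error.
    """
    descriptor = Descriptor(descriptor)
    form = SurvivalForm(form)
    obs_list = list(observations)
    if not obs_list:
        raise ValueError("no observations supplied")

    if descriptor is not Descriptor.DENSITY:
        attr = "basal_area" if descriptor is Descriptor.BASAL_COVER else "operc_area"
        n_missing = sum(
            1 for o in obs_list if o.N_start > 0 and math.isnan(getattr(o, attr))
        )
        if n_missing:
            raise ValueError(
                f"descriptor {descriptor.value} requires {attr}: "
                f"{n_missing} observation(s) have it missing"
            )

    X, y, s_raw, s30, tdays, dead = [], [], [], [], [], []
    shore, period, quadrat = [], [], []
    n_excluded = n_clipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # S > 1 clip warnings counted instead
        for o in obs_list:
            surv = interval_survival(o.N_start, o.N_end)
            if surv.excluded:
                n_excluded += 1
                continue
            if surv.clipped:
                n_clipped += 1
            s_base = standardize_survival(surv.value, o.T_days, base=base)
            # clip again: standardization can push a clipped value back to 1
            s_base = min(max(s_base, CLIP_EPS), 1.0 - CLIP_EPS)
            X.append(_descriptor_x(o, descriptor))
            y.append(linearize(form, s_base))
            s_raw.append(surv.raw)
            s30.append(s_base)
            tdays.append(o.T_days)
            dead.append(o.dead_cover)
            shore.append(o.shore)
            period.append(o.period)
            quadrat.append(o.quadrat)
    return DesignMatrix(
        X=np.asarray(X), y=np.asarray(y), s_raw=np.asarray(s_raw),
        s30=np.asarray(s30), T_days=np.asarray(tdays),
        dead_cover=np.asarray(dead), shore=shore, period=period,
        quadrat=quadrat, n_excluded=n_excluded, n_clipped=n_clipped,
    )


@dataclass(frozen=True)
class BackTransformed:
    """Survival-scale parameters recovered from a linear fit."""

    alpha: float
    beta: float
    admissible: bool
    message: str | None = None


def back_transform_params(
    form: SurvivalForm, intercept: float, slope: float
) -> BackTransformed:
    """Invert the linearization to recover ``(alpha, beta)``.

    exponential: ``alpha = e^intercept``, ``beta = -slope``;
    logistic: ``alpha' = e^intercept``, ``alpha = 1/(1 + alpha')``,
    ``beta = slope``; hyperbolic: ``alpha = 1/intercept``,
    ``beta = slope * alpha``.  Estimates implying ``alpha`` outside (0, 1]
    or ``beta < 0`` are flagged inadmissible but returned unclamped for
    diagnostics.
    """
    form = SurvivalForm(form)
    if form is SurvivalForm.EXPONENTIAL:
        alpha, beta = math.exp(intercept), -slope
    elif form is SurvivalForm.LOGISTIC:
        alpha, beta = 1.0 / (1.0 + math.exp(intercept)), slope
    else:
        if intercept == 0.0:
            return BackTransformed(
                alpha=math.nan, beta=math.nan, admissible=False,
                message="hyperbolic intercept is zero; alpha undefined",
            )
        alpha = 1.0 / intercept
        beta = slope * alpha
    msgs = []
    if not (0.0 < alpha <= 1.0):
        msgs.append(f"implied alpha={alpha:.6g} outside (0, 1]")
    if beta < 0.0:
        msgs.append(f"implied beta={beta:.6g} < 0")
    return BackTransformed(
        alpha=alpha, beta=beta, admissible=not msgs,
        message="; ".join(msgs) or None,
    )


def adjusted_r2(rss: float, tss: float, n: int, p: int) -> float:
    """Adjusted R² = 1 - (1 - R²)(n - 1)/(n - p - 1) with R² = 1 - rss/tss."""
    if tss <= 0:
        raise ValueError("tss must be > 0")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1, got n={n}, p={p}")
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Trend statistics for regression residuals (numbers only, no verdict)."""

    available: bool
    spearman_resid_x: float = math.nan
    spearman_absresid_x: float = math.nan
    n_sign_runs: int = 0


@dataclass
class FitResult:
    """Outcome of one linearized OLS fit."""

    form: SurvivalForm
    descriptor: Descriptor | None
    spec: ExtendedModelSpec | None
    coef: dict[str, float]
    alpha_hat: float | dict[str, float]
    beta_hat: float
    beta_dead_hat: float | None
    admissible: bool
    admissibility_message: str | None
    n: int
    k_coef: int
    rss: float
    tss: float
    adj_r2: float
    r2: float
    survival_scale_r2: float
    aic: float
    residuals: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    n_excluded: int = 0
    n_clipped: int = 0
    data_key: str = ""


def _gaussian_aic(n: int, rss: float, k_coef: int, tss: float = 0.0) -> float:
    """Gaussian-OLS AIC: ``n ln(RSS/n) + 2k`` with k counting coefficients
    plus one for the error variance.

    RSS is floored at 1e-10 of the TSS so that numerically exact fits (RSS
    at floating-point dust level) compare by the parameter penalty instead
    of by noise amplified through the log.
    """
    rss = max(rss, 1e-10 * tss, 1e-300)
    return n * math.log(rss / n) + 2 * (k_coef + 1)


def _survival_scale_r2(design: DesignMatrix, form: SurvivalForm,
                       y_fitted: np.ndarray) -> float:
    """R² of back-transformed predictions against observed interval survival."""
    form = SurvivalForm(form)
    if form is SurvivalForm.EXPONENTIAL:
        s30_hat = np.exp(y_fitted)
    elif form is SurvivalForm.LOGISTIC:
        s30_hat = 1.0 / (1.0 + np.exp(y_fitted))
    else:
        s30_hat = 1.0 / np.clip(y_fitted, 1.0, None)
    s_hat = s30_hat ** (design.T_days / BASE_DAYS)
    s_obs = np.clip(design.s_raw, 0.0, 1.0)
    rss = float(np.sum((s_obs - s_hat) ** 2))
    tss = float(np.sum((s_obs - s_obs.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else math.nan


def _finalize_fit(
    design: DesignMatrix,
    exog: np.ndarray,
    names: list[str],
    form: SurvivalForm,
    descriptor: Descriptor | None,
    spec: ExtendedModelSpec | None,
) -> FitResult:
    model = sm.OLS(design.y, exog)
    res = model.fit()
    coef = dict(zip(names, (float(c) for c in res.params)))
    rss = float(res.ssr)
    tss = float(res.centered_tss)
    n, k = design.n, exog.shape[1]

    if spec is not None and spec.alpha_by_period:
        alphas = {
            name.removeprefix("period:"): 1.0 / (1.0 + math.exp(coef[name]))
            for name in names if name.startswith("period:")
        }
        beta = coef["beta_live"]
        bt_admiss = all(0.0 < a <= 1.0 for a in alphas.values()) and beta >= 0.0
        msg = None
        alpha_hat: float | dict[str, float] = alphas
    else:
        bt = back_transform_params(form, coef[names[0]], coef[names[1]])
        alpha_hat, beta, bt_admiss, msg = bt.alpha, bt.beta, bt.admissible, bt.message
    beta_dead = coef.get("beta_dead")
    if beta_dead is not None and beta_dead < 0:
        bt_admiss = False
        msg = (msg + "; " if msg else "") + f"implied beta_dead={beta_dead:.6g} < 0"

    return FitResult(
        form=SurvivalForm(form), descriptor=descriptor, spec=spec, coef=coef,
        alpha_hat=alpha_hat, beta_hat=beta, beta_dead_hat=beta_dead,
        admissible=bt_admiss, admissibility_message=msg,
        n=n, k_coef=k, rss=rss, tss=tss,
        adj_r2=adjusted_r2(rss, tss, n, k - 1) if n > k else math.nan,
        r2=1.0 - rss / tss if tss > 0 else math.nan,
        survival_scale_r2=_survival_scale_r2(design, form, np.asarray(res.fittedvalues)),
        aic=_gaussian_aic(n, rss, k, tss),
        residuals=np.asarray(res.resid), X=design.X,
        fitted=np.asarray(res.fittedvalues),
        n_excluded=design.n_excluded, n_clipped=design.n_clipped,
        data_key=design.data_key(),
    )


def fit_form(
    observations: Iterable[QuadratObservation],
    form: SurvivalForm,
    descriptor: Descriptor,
    base: float = BASE_DAYS,
) -> FitResult:
    """Fit one survival form against one resource-use descriptor by OLS.

    The transformed base-interval survival is regressed on the descriptor
    ``X`` with an intercept; parameters are back-transformed to the survival
    scale.  Intended to be applied per shore (the study never pools shores).
    """
    design = build_design(observations, descriptor, form, base=base)
    if design.n < 3:
        raise ValueError(f"need >= 3 usable observations, have {design.n}")
    if np.ptp(design.X) == 0.0:
        raise ValueError(
            f"descriptor {Descriptor(descriptor).value} is constant across "
            f"observations; design is rank deficient"
        )
    exog = np.column_stack([np.ones(design.n), design.X])
    return _finalize_fit(design, exog, ["intercept", "slope"],
                         form, Descriptor(descriptor), None)


def residual_trend(fit: FitResult) -> ResidualDiagnostics:
    """Trend diagnostics for a fit's residuals.

    Reports Spearman rank correlations of the residuals and of their
    absolute values against the predictor, plus the number of sign runs
    along increasing X.  Numbers only — no pass/fail verdict.  Fits with
    fewer than 5 observations are marked unavailable.
    """
    r = fit.residuals
    if r.size < 5:
        return ResidualDiagnostics(available=False)
    order = np.argsort(fit.X, kind="stable")
    r_sorted = r[order]
    # residuals at floating-point dust level are an exact fit, not a trend
    noise_floor = 1e-10 * max(1.0, float(np.ptp(fit.fitted)))
    if np.max(np.abs(r)) <= noise_floor:
        return ResidualDiagnostics(
            available=True, spearman_resid_x=0.0, spearman_absresid_x=0.0,
            n_sign_runs=0,
        )
    if np.ptp(r) == 0.0:
        rho_r, rho_a = 0.0, 0.0
    else:
        rho_r = float(stats.spearmanr(fit.X, r).statistic)
        rho_a = float(stats.spearmanr(fit.X, np.abs(r)).statistic)
    signs = np.sign(r_sorted)
    signs = signs[signs != 0]
    n_runs = int(1 + np.sum(signs[1:] != signs[:-1])) if signs.size else 0
    return ResidualDiagnostics(
        available=True, spearman_resid_x=rho_r, spearman_absresid_x=rho_a,
        n_sign_runs=n_runs,
    )


def fit_extended(
    observations: Iterable[QuadratObservation],
    spec: ExtendedModelSpec,
    base: float = BASE_DAYS,
) -> FitResult:
    """Fit the extended logistic model for one shore.

    The response is the logit-linearized base-interval survival; the design
    holds period-specific intercepts (when ``alpha_by_period``) or a single
    intercept, the live operculum-cover term ``O*N``, and optionally the
    dead-shell cover.  With both switches off this reduces exactly to
    ``fit_form(logistic, operc_cover)``.
    """
    design = build_design(observations, Descriptor.OPERC_COVER,
                          SurvivalForm.LOGISTIC, base=base)
    periods = list(dict.fromkeys(design.period))  # first-appearance order
    if spec.alpha_by_period:
        if len(periods) < 2:
            raise ValueError("alpha_by_period requires >= 2 census periods")
        counts = {p: design.period.count(p) for p in periods}
        thin = [p for p, c in counts.items() if c < 3]
        if thin:
            raise ValueError(f"period(s) with < 3 observations: {thin}")
        cols = [np.asarray([1.0 if q == p else 0.0 for q in design.period])
                for p in periods]
        names = [f"period:{p}" for p in periods]
    else:
        cols = [np.ones(design.n)]
        names = ["intercept"]
    cols.append(design.X)
    names.append("beta_live" if spec.alpha_by_period or spec.include_dead_cover
                 else "slope")
    if spec.include_dead_cover:
        cols.append(design.dead_cover)
        names.append("beta_dead")
    exog = np.column_stack(cols)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("extended design is rank deficient")
    return _finalize_fit(design, exog, names, SurvivalForm.LOGISTIC,
                         Descriptor.OPERC_COVER, spec)


def aic(fit: FitResult) -> float:
    """Gaussian-OLS AIC of a fit (``n ln(RSS/n) + 2k``, k = coefficients + 1)."""
    return fit.aic


def select_by_aic(
    fits: Sequence[FitResult], parsimony_margin: float = 2.0
) -> FitResult:
    """Select a fit by AIC with the standard parsimony convention.

    Models within ``parsimony_margin`` AIC units of the minimum are treated
    as equivalently supported, and the most parsimonious of them (fewest
    coefficients) is returned — the usual "substantial support" reading of
    AIC differences in ecology.  Plain lowest-AIC selection accepts a
    spurious extra parameter roughly 16% of the time; the 2-unit margin
    restores parsimony without hiding genuinely better models.  Set
    ``parsimony_margin=0`` for strict lowest-AIC (exact ties then still go
    to the simpler model).

    All candidates must have been fitted on the identical observation set
    (checked via a fingerprint of the shared response and cover data).
    """
    if not fits:
        raise ValueError("no candidate fits supplied")
    if parsimony_margin < 0:
        raise ValueError("parsimony_margin must be >= 0")
    keys = {f.data_key for f in fits}
    if len(keys) > 1:
        raise ValueError("candidate fits were computed on different data")
    best = min(f.aic for f in fits)
    supported = [f for f in fits if f.aic <= best + parsimony_margin]
    return min(supported, key=lambda f: (f.k_coef, f.aic))


def fit_table(
    observations: Sequence[QuadratObservation],
    forms: Sequence[SurvivalForm] = tuple(SurvivalForm),
    descriptors: Sequence[Descriptor] = tuple(Descriptor),
) -> pd.DataFrame:
    """Adjusted-R² table over form × descriptor, fitted per shore.

    Returns a tidy frame (shore, descriptor, form, adj_r2, alpha, beta,
    admissible) — the machinery behind a forms-by-descriptors comparison
    table.
    """
    rows = []
    shores = sorted({o.shore for o in observations})
    for shore in shores:
        obs = [o for o in observations if o.shore == shore]
        for d in descriptors:
            for f in forms:
                fit = fit_form(obs, f, d)
                rows.append({
                    "shore": shore,
                    "descriptor": Descriptor(d).value,
                    "form": SurvivalForm(f).value,
                    "adj_r2": fit.adj_r2,
                    "alpha": fit.alpha_hat,
                    "beta": fit.beta_hat,
                    "admissible": fit.admissible,
                })
    return pd.DataFrame(rows)
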