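"""Cox proportional-hazards modelling of the methylation index.

The methylation index enters the hazard model in four codings — binary,
tertile, quintile (reference: unmethylated, index 0) and continuous — with
age, Karnofsky performance status, IDH1 mutation and extent of resection as
optional covariates.  Nonlinearity of the index effect is modelled with
restricted cubic splines (natural cubic, linear beyond the boundary knots),
unpenalized B-splines, or difference-penalized B-splines (P-splines), all
inside the Cox partial likelihood; functional form and proportionality are
checked with smoothed martingale residuals and scaled Schoenfeld residuals.

Ordinary fits, the Schoenfeld test and martingale residuals are delegated to
lifelines; the spline bases, the penalized fits and the global score test
use the in-package partial-likelihood engine (:mod:`methindex._cox`).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from ._cox import (
    EngineFit,
    breslow_baseline,
    fit_cox_newton,
    score_test_at_null,
)
from .caller import categorize

__all__ = [
    "ModelSpec",
    "CoxFitResult",
    "SplineFitResult",
    "ResidualDiagnostics",
    "build_design",
    "fit_cox",
    "rcs_basis",
    "bspline_basis",
    "fit_spline_cox",
    "martingale_diagnostics",
    "schoenfeld_test",
    "adjusted_curves",
    "report_tables",
    "render_table_text",
]

CODINGS = ("binary", "tertile", "quintile", "continuous")
ENDPOINTS = ("os", "pfs")
COVARIATES = ("age", "kps", "idh1", "resection")

_TERTILE_LEVELS = ("1-6", "7-12", "13-17")
_QUINTILE_LEVELS = ("1-3", "4-6", "7-9", "10-13", "14-17")
_RESECTION_DUMMIES = ("res_subtotal", "res_gross_total", "res_unknown")
_RES_LEVEL = {
    "res_subtotal": "subtotal",
    "res_gross_total": "gross_total",
    "res_unknown": "unknown",
}


@dataclass(frozen=True)
class ModelSpec:
    endpoint: str = "os"
    coding: str = "tertile"
    covariates: tuple[str, ...] = ("age", "kps", "idh1")
    ties: str = "efron"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        if self.coding not in CODINGS:
            raise ValueError(f"coding must be one of {CODINGS}")
        bad = set(self.covariates) - set(COVARIATES)
        if bad:
            raise ValueError(f"unknown covariates {sorted(bad)}")
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")


@dataclass
class CoxFitResult:
    spec: ModelSpec
    summary: pd.DataFrame  # index: term; coef, hr, se, ci_lower, ci_upper, p
    global_tests: dict  # name -> (statistic, df, p)
    concordance: float
    concordance_se: Optional[float]
    n: int
    n_events: int
    meth_terms: tuple[str, ...]
    covariate_terms: tuple[str, ...]
    warnings: tuple[str, ...] = ()
    loglik: float = float("nan")
    _design: Optional[pd.DataFrame] = None
    _duration_col: str = ""
    _event_col: str = ""
    _cph: object = None  # lifelines CoxPHFitter when backend == lifelines
    backend: str = "lifelines"

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.summary.index)

    def params(self) -> pd.Series:
        return self.summary["coef"]


@dataclass
class SplineFitResult:
    basis: str  # "rcs" | "bspline" | "pspline"
    knots: np.ndarray
    spline_terms: tuple[str, ...]
    coef: pd.Series
    cov: pd.DataFrame
    grid: np.ndarray  # index values 0..17
    log_hr: np.ndarray  # pointwise log-HR relative to index 0
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    chi2: float
    df: float
    p: float
    edf: float
    penalty_weight: float = 0.0
    converged: bool = True
    chi2_nonlinear: Optional[float] = None  # RCS only: Wald on nonlinear terms
    df_nonlinear: Optional[int] = None
    p_nonlinear: Optional[float] = None

    def curve_argmin(self) -> float:
        """Index value at which the fitted log-hazard curve is lowest."""
        return float(self.grid[int(np.argmin(self.log_hr))])


@dataclass
class ResidualDiagnostics:
    martingale: Optional[pd.DataFrame] = None  # index, residual per patient
    smooth: Optional[pd.DataFrame] = None  # x, y of the smoothed curve
    bandwidth: Optional[float] = None
    schoenfeld: Optional[pd.DataFrame] = None  # per-term chi2, df, p
    time_transform: Optional[str] = None
    flagged_terms: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, tuple[str, ...], tuple[str, ...], str, str]:
    """Assemble the regression frame for one model spec.

    Returns ``(frame, meth_terms, covariate_terms, duration_col, event_col)``.
    The unmethylated group (index 0) is the reference for every categorical
    coding; resection enters as dummies against biopsy with the explicit
    ``unknown`` level kept.
    """
    duration_col = f"{spec.endpoint}_months"
    event_col = f"{spec.endpoint}_event"
    for col in (duration_col, event_col, "index"):
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks required column {col!r}")
    frame = pd.DataFrame(
        {duration_col: cohort[duration_col], event_col: cohort[event_col]}
    )
    idx = cohort["index"].astype(int)
    if (idx < 0).any() or (idx > 17).any():
        raise ValueError("index outside [0, 17]")

    meth_terms: list[str] = []
    if spec.coding == "binary":
        frame["meth_any"] = (idx > 0).astype(float)
        meth_terms = ["meth_any"]
    elif spec.coding in ("tertile", "quintile"):
        labels = idx.map(
            lambda i: categorize(int(i))[1 if spec.coding == "tertile" else 2]
        )
        levels = _TERTILE_LEVELS if spec.coding == "tertile" else _QUINTILE_LEVELS
        for lv in levels:
            name = f"meth_{lv}"
            frame[name] = (labels == lv).astype(float)
            meth_terms.append(name)
    else:
        frame["index"] = idx.astype(float)
        meth_terms = ["index"]

    covariate_terms: list[str] = []
    for cov in spec.covariates:
        if cov == "resection":
            for name in _RESECTION_DUMMIES:
                frame[name] = (cohort["resection"] == _RES_LEVEL[name]).astype(float)
                covariate_terms.append(name)
        else:
            frame[cov] = cohort[cov].astype(float)
            covariate_terms.append(cov)
    return frame, tuple(meth_terms), tuple(covariate_terms), duration_col, event_col


def _concordance_se(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray, cap: int = 3000
) -> Optional[float]:
    """Jackknife-type standard error of the concordance index.

    Pairwise (O(n^2)); skipped above ``cap`` subjects (returns None).
    """
    n = len(time)
    if n > cap or n < 3:
        return None
    ti, tj = time[:, None], time[None, :]
    ei = event[:, None]
    comparable = (ti < tj) & (ei == 1)
    ri, rj = risk[:, None], risk[None, :]
    weight = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0)) * comparable
    s_den = comparable.sum()
    if s_den == 0:
        return None
    s_num = weight.sum()
    num_i = weight.sum(axis=1) + weight.sum(axis=0)
    den_i = comparable.sum(axis=1) + comparable.sum(axis=0)
    den_loo = s_den - den_i
    ok = den_loo > 0
    c_loo = (s_num - num_i[ok]) / den_loo[ok]
    m = int(ok.sum())
    if m < 3:
        return None
    return float(np.sqrt((m - 1) / m * ((c_loo - c_loo.mean()) ** 2).sum()))


def fit_cox(cohort: pd.DataFrame, spec: ModelSpec) -> CoxFitResult:
    """Fit a Cox proportional-hazards model under one index coding.

    Wald confidence intervals on the hazard-ratio scale; global likelihood
    ratio, Wald and score (log-rank) chi-squares over all terms; Harrell's
    concordance.  Degenerate methylation levels (present but with zero
    events) are reported as warnings on the result, not errors.
    """
    frame, meth_terms, cov_terms, dcol, ecol = build_design(cohort, spec)
    n = len(frame)
    n_events = int(frame[ecol].sum())
    if n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    x_cols = list(meth_terms) + list(cov_terms)
    warnings: list[str] = []
    for col in list(x_cols):
        if frame[col].nunique() <= 1:
            warnings.append(f"constant column {col!r} dropped from the model")
            x_cols.remove(col)
    for col in [c for c in x_cols if c.startswith("meth_")]:
        level_events = frame.loc[frame[col] == 1.0, ecol].sum()
        if frame[col].sum() == 0:
            raise ValueError(f"coding level {col!r} has no subjects")
        if level_events == 0:
            warnings.append(
                f"level {col!r} has subjects but zero events (possible separation)"
            )

    X = frame[x_cols].to_numpy(float)
    time = frame[dcol].to_numpy(float)
    event = frame[ecol].to_numpy(int)

    if spec.ties == "efron":
        from lifelines import CoxPHFitter

        cph = CoxPHFitter()
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            cph.fit(frame[[dcol, ecol] + x_cols], duration_col=dcol, event_col=ecol)
        coef = cph.params_.reindex(x_cols)
        se = cph.standard_errors_.reindex(x_cols)
        V = cph.variance_matrix_.loc[x_cols, x_cols].to_numpy()
        loglik = float(cph.log_likelihood_)
        lr = cph.log_likelihood_ratio_test()
        lr_stat, lr_p = float(lr.test_statistic), float(lr.p_value)
        concordance = float(cph.concordance_index_)
        backend, handle = "lifelines", cph
    else:
        eng = fit_cox_newton(X, time, event, ties="breslow")
        coef = pd.Series(eng.beta, index=x_cols)
        se = pd.Series(np.sqrt(np.diag(eng.cov)), index=x_cols)
        V = eng.cov
        loglik = eng.loglik
        lr_stat = 2.0 * (eng.loglik - eng.loglik_null)
        lr_p = float(stats.chi2.sf(lr_stat, len(x_cols)))
        from lifelines.utils import concordance_index

        concordance = float(concordance_index(time, -(X @ eng.beta), event))
        backend, handle = "engine", eng

    z = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "se": se,
            "ci_lower": np.exp(coef - z * se),
            "ci_upper": np.exp(coef + z * se),
            "p": 2.0 * stats.norm.sf(np.abs(coef / se)),
        }
    )
    p_total = len(x_cols)
    wald_stat = float(coef.to_numpy() @ np.linalg.solve(V, coef.to_numpy()))
    score_stat, _ = score_test_at_null(X, time, event, ties=spec.ties)
    global_tests = {
        "likelihood_ratio": (lr_stat, p_total, lr_p),
        "wald": (wald_stat, p_total, float(stats.chi2.sf(wald_stat, p_total))),
        "logrank": (
            score_stat,
            p_total,
            float(stats.chi2.sf(score_stat, p_total)),
        ),
    }
    risk = X @ coef.to_numpy()
    return CoxFitResult(
        spec=spec,
        summary=summary,
        global_tests=global_tests,
        concordance=concordance,
        concordance_se=_concordance_se(risk, time, event),
        n=n,
        n_events=n_events,
        meth_terms=tuple(t for t in meth_terms if t in x_cols),
        covariate_terms=tuple(t for t in cov_terms if t in x_cols),
        warnings=tuple(warnings),
        loglik=loglik,
        _design=frame[[dcol, ecol] + x_cols],
        _duration_col=dcol,
        _event_col=ecol,
        _cph=handle if backend == "lifelines" else None,
        backend=backend,
    )


# ---------------------------------------------------------------------------
# spline bases
# ---------------------------------------------------------------------------

#: default knot placement quantiles (Harrell's convention)
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def _default_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Quantile knots; falls back to quantiles of the distinct values when
    heavy ties (e.g. a large unmethylated group at index 0) make the plain
    quantiles degenerate."""
    q = np.array(_KNOT_QUANTILES.get(n_knots, tuple(np.linspace(0.05, 0.95, n_knots))))
    knots = np.quantile(x, q)
    if np.all(np.diff(knots) > 0):
        return knots
    distinct = np.unique(x)
    knots = np.quantile(distinct, q)
    if np.all(np.diff(knots) > 0):
        return knots
    raise ValueError("too few distinct values for the requested knot count")


def rcs_basis(
    x: Sequence[float],
    n_knots: int = 5,
    knots: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Restricted (natural) cubic spline basis in truncated-power form.

    Returns ``(basis, knots)`` where the basis has ``n_knots - 1`` columns:
    the linear term plus ``n_knots - 2`` nonlinear terms constructed so the
    fitted function is linear beyond the boundary knots.  Nonlinear terms
    are scaled by ``(k_last - k_first)^2`` (Harrell's normalization).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if n_knots < 3:
            raise ValueError("n_knots must be >= 3")
        if len(np.unique(x)) < n_knots:
            raise ValueError("fewer distinct values than knots")
        knots = _default_knots(x, n_knots)
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 knots")
    tau = (knots[-1] - knots[0]) ** 2
    cols = [x]

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    for j in range(k - 2):
        term = (
            pos3(x - knots[j])
            - pos3(x - knots[-2]) * (knots[-1] - knots[j]) / (knots[-1] - knots[-2])
            + pos3(x - knots[-1]) * (knots[-2] - knots[j]) / (knots[-1] - knots[-2])
        ) / tau
        cols.append(term)
    return np.column_stack(cols), knots


def bspline_basis(
    x: Sequence[float],
    n_knots: int = 5,
    knots: Optional[Sequence[float]] = None,
    degree: int = 3,
    drop_first: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with clamped boundary knots.

    Interior knots default to quantiles (same placement rule as the RCS);
    the first column is dropped so the basis is identified inside a Cox
    model, where any constant direction is unidentifiable.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = _default_knots(x, n_knots)
    knots = np.asarray(knots, dtype=float)
    lo, hi = knots[0], knots[-1]
    interior = knots[1:-1]
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    xc = np.clip(x, lo, hi)
    design = BSpline.design_matrix(xc, t, degree).toarray()
    if drop_first:
        design = design[:, 1:]
    return design, knots


def _difference_penalty(m: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(m), n=order, axis=0)
    return D.T @ D


# ---------------------------------------------------------------------------
# spline Cox fits
# ---------------------------------------------------------------------------


def fit_spline_cox(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    basis: str = "rcs",
    n_knots: int = 5,
    knots: Optional[Sequence[float]] = None,
    n_bspline: int = 12,
    penalty_grid: Optional[Sequence[float]] = None,
    grid: Optional[np.ndarray] = None,
) -> SplineFitResult:
    """Fit a Cox model with a spline in the methylation index.

    ``basis``:

    * ``"rcs"`` — restricted cubic spline, ``n_knots`` knots (default 5),
      unpenalized;
    * ``"bspline"`` — cubic B-spline on the same knots, unpenalized;
    * ``"pspline"`` — richer cubic B-spline basis (``n_bspline`` functions,
      equally spaced interior knots) with a second-difference penalty whose
      weight is chosen on an AIC grid.

    The result carries the pointwise log hazard ratio over the index range,
    referenced to index 0 (the curve is exactly 0 there), with a Wald 95%
    band, plus an overall chi-square for the spline block.
    """
    if spec.coding != "continuous":
        raise ValueError("spline fits require the continuous coding")
    if basis not in ("rcs", "bspline", "pspline"):
        raise ValueError("basis must be rcs, bspline or pspline")
    frame, _, cov_terms, dcol, ecol = build_design(cohort, spec)
    x = frame["index"].to_numpy(float)
    time = frame[dcol].to_numpy(float)
    event = frame[ecol].to_numpy(int)
    if grid is None:
        grid = np.linspace(0.0, 17.0, 171)
    grid = np.asarray(grid, dtype=float)

    penalty = None
    penalty_weight = 0.0
    if basis == "rcs":
        B, used_knots = rcs_basis(x, n_knots=n_knots, knots=knots)

        def eval_basis(g):
            return rcs_basis(g, knots=used_knots)[0]

    elif basis == "bspline":
        B, used_knots = bspline_basis(x, n_knots=n_knots, knots=knots)

        def eval_basis(g):
            return bspline_basis(g, knots=used_knots)[0]

    else:
        lo, hi = float(x.min()), float(x.max())
        n_interior = max(n_bspline - 4, 1)
        used_knots = np.linspace(lo, hi, n_interior + 2)
        B, _ = bspline_basis(x, knots=used_knots)

        def eval_basis(g):
            return bspline_basis(g, knots=used_knots)[0]

        m_full = B.shape[1] + 1  # before dropping the first column
        P_full = _difference_penalty(m_full, order=2)
        P_spline = P_full[1:, 1:]

    spline_terms = tuple(f"spline_{i}" for i in range(B.shape[1]))
    Xcov = frame[list(cov_terms)].to_numpy(float) if cov_terms else np.empty((len(x), 0))
    X = np.hstack([B, Xcov])
    names = list(spline_terms) + list(cov_terms)
    p = X.shape[1]

    if basis == "pspline":
        if penalty_grid is None:
            penalty_grid = np.logspace(-2, 4, 13)
        best = None
        for lam in penalty_grid:
            P = np.zeros((p, p))
            P[: B.shape[1], : B.shape[1]] = lam * P_spline
            eng = fit_cox_newton(X, time, event, ties=spec.ties, penalty=P)
            aic = -2.0 * eng.loglik + 2.0 * eng.edf
            if best is None or aic < best[0]:
                best = (aic, lam, eng)
        _, penalty_weight, fit = best
    else:
        fit = fit_cox_newton(X, time, event, ties=spec.ties)

    coef = pd.Series(fit.beta, index=names)
    cov = pd.DataFrame(fit.cov, index=names, columns=names)

    nb = B.shape[1]
    delta = eval_basis(grid) - eval_basis(np.zeros(1))
    bs = fit.beta[:nb]
    Vs = fit.cov[:nb, :nb]
    log_hr = delta @ bs
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", delta, Vs, delta), 0.0))
    z = stats.norm.ppf(0.975)
    chi2 = float(bs @ np.linalg.solve(Vs, bs))
    dof = fit.edf - len(cov_terms) if basis == "pspline" else float(nb)
    chi2_nl = df_nl = p_nl = None
    if basis == "rcs" and nb > 1:
        bnl, Vnl = fit.beta[1:nb], fit.cov[1:nb, 1:nb]
        chi2_nl = float(bnl @ np.linalg.solve(Vnl, bnl))
        df_nl = nb - 1
        p_nl = float(stats.chi2.sf(chi2_nl, df_nl))
    return SplineFitResult(
        basis=basis,
        knots=np.asarray(used_knots, dtype=float),
        spline_terms=spline_terms,
        coef=coef,
        cov=cov,
        grid=grid,
        log_hr=log_hr,
        ci_lower=log_hr - z * se,
        ci_upper=log_hr + z * se,
        chi2=chi2,
        df=dof,
        p=float(stats.chi2.sf(chi2, dof)),
        edf=fit.edf,
        penalty_weight=float(penalty_weight),
        converged=fit.converged,
        chi2_nonlinear=chi2_nl,
        df_nonlinear=df_nl,
        p_nonlinear=p_nl,
    )


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------


def martingale_diagnostics(
    cohort: pd.DataFrame,
    endpoint: str = "os",
    unadjusted: bool = True,
    covariates: tuple[str, ...] = ("age", "kps", "idh1"),
    frac: float = 0.35,
) -> ResidualDiagnostics:
    """Martingale residuals against the methylation index, LOWESS-smoothed.

    With ``unadjusted=True`` (the default) residuals come from the null
    model — event indicator minus the Nelson–Aalen cumulative hazard at the
    observed time — so the smoothed trend over the index reveals the
    functional form of the index effect before any modelling choice.
    Otherwise residuals come from a fitted continuous-coding Cox model.
    """
    dcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    time = cohort[dcol].to_numpy(float)
    event = cohort[ecol].to_numpy(int)
    index = cohort["index"].to_numpy(float)
    if unadjusted:
        from lifelines import NelsonAalenFitter

        naf = NelsonAalenFitter()
        naf.fit(time, event_observed=event)
        cumhaz = naf.cumulative_hazard_at_times(time).to_numpy()
        resid = event - cumhaz
    else:
        fit = fit_cox(
            cohort, ModelSpec(endpoint=endpoint, coding="continuous", covariates=covariates)
        )
        res = fit._cph.compute_residuals(fit._design, kind="martingale")
        resid = res["martingale"].reindex(fit._design.index).to_numpy()

    from statsmodels.nonparametric.smoothers_lowess import lowess

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # heavy x-ties (the large unmethylated group) trigger a harmless
        # divide warning inside local windows
        _warnings.simplefilter("ignore", RuntimeWarning)
        sm = lowess(resid, index, frac=frac, return_sorted=True)
    return ResidualDiagnostics(
        martingale=pd.DataFrame({"index": index, "residual": resid}),
        smooth=pd.DataFrame({"x": sm[:, 0], "y": sm[:, 1]}),
        bandwidth=frac,
    )


def schoenfeld_test(
    fit: CoxFitResult, time_transform: str = "km"
) -> ResidualDiagnostics:
    """Proportional-hazards check: slope of scaled Schoenfeld residuals
    against transformed time (Kaplan–Meier transform by default), one
    chi-square (1 df) per model term.  Terms dropped at fit time (constant
    columns) are reported as flagged, their test undefined.
    """
    if fit.n_events < 2:
        raise ValueError("Schoenfeld test undefined with fewer than 2 events")
    if fit.backend != "lifelines":
        raise NotImplementedError("Schoenfeld test requires an Efron/lifelines fit")
    from lifelines.statistics import proportional_hazard_test

    result = proportional_hazard_test(
        fit._cph, fit._design, time_transform=time_transform
    )
    summ = result.summary.copy()
    summ = summ.rename(columns={"test_statistic": "chi2"})
    summ["df"] = 1
    flagged = tuple(
        w.split("'")[1] for w in fit.warnings if w.startswith("constant column")
    )
    return ResidualDiagnostics(
        schoenfeld=summ[["chi2", "df", "p"]],
        time_transform=time_transform,
        flagged_terms=flagged,
    )


# ---------------------------------------------------------------------------
# adjusted survival curves and tables
# ---------------------------------------------------------------------------


def adjusted_curves(
    fit: CoxFitResult, groups: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Cox-adjusted survival curves per methylation level.

    The Breslow baseline cumulative hazard is raised to ``exp(lp)`` with the
    linear predictor evaluated at reference covariate values — means for
    numeric covariates, the modal dummy pattern for resection — varying only
    the methylation level.  Returns a step-function table (rows: time,
    starting at 0 with survival 1; columns: group labels).
    """
    if fit.spec.coding == "continuous":
        raise ValueError("adjusted curves require a categorical coding")
    design = fit._design
    x_cols = list(fit.meth_terms) + list(fit.covariate_terms)
    X = design[x_cols].to_numpy(float)
    beta = fit.summary["coef"].reindex(x_cols).to_numpy()
    times, H0 = breslow_baseline(
        beta,
        X,
        design[fit._duration_col].to_numpy(float),
        design[fit._event_col].to_numpy(int),
    )

    levels = ["unmethylated"] + [t.replace("meth_", "") for t in fit.meth_terms]
    if fit.spec.coding == "binary":
        levels = ["unmethylated", "methylated"]
    if groups is None:
        groups = levels
    unknown = set(groups) - set(levels)
    if unknown:
        raise ValueError(f"groups {sorted(unknown)} absent from the fitted model")

    ref = {}
    for col in fit.covariate_terms:
        ref[col] = float(design[col].mean())
    res_cols = [c for c in fit.covariate_terms if c.startswith("res_")]
    if res_cols:
        # modal resection pattern rather than dummy means
        patterns = design[res_cols].apply(tuple, axis=1)
        mode = patterns.mode().iloc[0]
        for col, v in zip(res_cols, mode):
            ref[col] = float(v)

    out = {"time": np.r_[0.0, times]}
    for g in groups:
        row = dict.fromkeys(x_cols, 0.0)
        row.update(ref)
        for t in fit.meth_terms:
            row[t] = 0.0
        if g != "unmethylated":
            key = "meth_any" if fit.spec.coding == "binary" else f"meth_{g}"
            row[key] = 1.0
        lp = float(np.dot([row[c] for c in x_cols], beta))
        out[g] = np.r_[1.0, np.exp(-H0 * np.exp(lp))]
    return pd.DataFrame(out).set_index("time")


_TEST_LABEL = {
    "likelihood_ratio": "LR test",
    "wald": "Wald test",
    "logrank": "Logrank test",
}


def report_tables(fits: Sequence[CoxFitResult]) -> pd.DataFrame:
    """Summarize fits as one long table, one block per model coding.

    Reference rows are labelled explicitly; the per-model global tests and
    concordance are appended to each block.
    """
    rows = []
    for fit in fits:
        model = f"{fit.spec.endpoint.upper()} {fit.spec.coding}"
        if fit.spec.coding != "continuous":
            rows.append(
                {
                    "model": model,
                    "variable": "unmethylated (reference)",
                    "hr": "Reference",
                    "ci": "Reference",
                    "p": "Reference",
                }
            )
        for term, r in fit.summary.iterrows():
            rows.append(
                {
                    "model": model,
                    "variable": term,
                    "hr": f"{r['hr']:.2f}",
                    "ci": f"{r['ci_lower']:.2f}-{r['ci_upper']:.2f}",
                    "p": f"{r['p']:.3g}",
                }
            )
        for name, (stat, df, p) in fit.global_tests.items():
            rows.append(
                {
                    "model": model,
                    "variable": _TEST_LABEL[name],
                    "hr": f"{stat:.2f}",
                    "ci": f"df={df}",
                    "p": f"{p:.2g}",
                }
            )
        conc = f"{fit.concordance:.2f}"
        if fit.concordance_se is not None:
            conc += f" ({fit.concordance_se:.3f})"
        rows.append(
            {"model": model, "variable": "Concordance (SE)", "hr": conc, "ci": "", "p": ""}
        )
    return pd.DataFrame(rows, columns=["model", "variable", "hr", "ci", "p"])


def render_table_text(table: pd.DataFrame) -> str:
    """Plain-text rendering of a report table."""
    if table.empty:
        return "model  variable  hr  ci  p\n"
    return table.to_string(index=False) + "\n"
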