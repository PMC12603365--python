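"""Crude and adjusted association estimation.

Implements the estimation layer of the analysis: closed-form 2x2 odds
ratios with Woolf (log-scale) confidence intervals, two-group comparison
tests, maximum-likelihood and Firth-penalized logistic regression with a
shared Newton solver, covariate-adjusted exposure effects, and
interaction-term subgroup scans.

The Firth fit maximizes the Jeffreys-prior penalized likelihood
``l*(beta) = l(beta) + 0.5 * log det I(beta)`` by modifying the score with
the hat-matrix diagonal; it yields finite estimates under complete or
quasi-complete separation, where plain maximum likelihood diverges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

# Woolf interval uses the conventional 1.96 normal quantile.
Z95 = 1.96

#: Predefined adjustment set for the multivariable models, in fixed order.
#: ``stroke_subtype`` is categorical and is expanded to reference-coded
#: indicators (large-artery atherosclerosis, the most frequent level, is
#: the reference).
DEFAULT_COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "admission_nihss",
    "bmi",
    "pre_mrs",
    "previous_stroke",
    "hypertension",
    "diabetes",
    "hyperlipidaemia",
    "atrial_fibrillation",
    "coronary_artery_disease",
    "smoking",
    "stroke_subtype",
    "revascularization",
    "haemoglobin",
    "total_cholesterol",
    "infarct_volume_pct_imputed",
)

CATEGORICAL_COVARIATES: tuple[str, ...] = ("stroke_subtype", "sex")


class SeparationError(RuntimeError):
    """Raised when maximum likelihood diverges under (quasi-)separation.

    The message advises refitting with ``method='firth'``, which is
    guaranteed to return finite estimates.
    """


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposed-event (a), exposed-nonevent (b), unexposed-event (c),
    unexposed-nonevent (d) counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class EffectEstimate:
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    scale_note: str = ""
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class LogisticFit:
    """A fitted logistic model (maximum likelihood or Firth-penalized)."""

    terms: list[str]
    beta: np.ndarray
    cov: np.ndarray
    method: str
    converged: bool
    iterations: int
    loglik: float
    separation_detected: bool = False
    dropped_terms: list[str] = field(default_factory=list)
    n_obs: int = 0
    n_events: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald(self) -> pd.DataFrame:
        """Per-term Wald z statistics, p-values and 95% CIs (OR scale)."""
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": se,
                "or": np.exp(self.beta),
                "ci_low": np.exp(self.beta - Z95 * se),
                "ci_high": np.exp(self.beta + Z95 * se),
                "z": z,
                "p": p,
            }
        )

    def term_effect(self, term: str, invert: bool = False, scale_note: str = "") -> EffectEstimate:
        """Odds-ratio estimate for one coefficient.

        ``invert=True`` negates the coefficient first, e.g. to report a
        continuous exposure per 1 unit *decrease*.
        """
        i = self.terms.index(term)
        b = -self.beta[i] if invert else self.beta[i]
        se = self.se[i]
        z = b / se if se > 0 else np.inf
        return EffectEstimate(
            or_point=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * se)),
            ci_high=float(np.exp(b + Z95 * se)),
            p=float(2.0 * stats.norm.sf(abs(z))),
            scale_note=scale_note,
        )


@dataclass(frozen=True)
class GroupComparison:
    test: str  # chi2 | fisher | t | mannwhitney
    statistic: float
    p: float


def odds_ratio_2x2(table: ContingencyTable2x2) -> EffectEstimate:
    """Odds ratio ad/bc with the Woolf logit 95% interval.

    A zero cell triggers the Haldane–Anscombe correction (0.5 added to
    every cell), flagged on the returned estimate.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = False
    if table.has_zero_cell:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
        logger.warning("zero cell in 2x2 table; Haldane-Anscombe 0.5 correction applied")
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("2x2 table has a zero margin; odds ratio undefined")
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return EffectEstimate(
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        continuity_corrected=corrected,
    )


def compare_groups(values: np.ndarray, group: np.ndarray, kind: str = "auto") -> GroupComparison:
    """Two-group comparison with the field's usual test menu.

    Binary data: Pearson chi-square, falling back to Fisher's exact test
    when any expected cell count is below 5.  Continuous data: Student's
    t-test when both groups pass a normality screen (D'Agostino, p > 0.05,
    n >= 20), else the Mann-Whitney U test.
    """
    values = np.asarray(values)
    group = np.asarray(group)
    mask = ~(pd.isna(values) | pd.isna(group))
    values, group = values[mask], group[mask]
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {len(levels)}")
    g0 = values[group == levels[0]]
    g1 = values[group == levels[1]]

    if kind == "auto":
        uniq = np.unique(values)
        kind = "binary" if len(uniq) <= 2 and set(np.asarray(uniq, dtype=float)) <= {0.0, 1.0} else "continuous"

    if kind == "binary":
        tab = np.array(
            [
                [np.sum(g1 == 1), np.sum(g1 == 0)],
                [np.sum(g0 == 1), np.sum(g0 == 0)],
            ],
            dtype=float,
        )
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        if (expected < 5).any():
            odds, p = stats.fisher_exact(tab)
            return GroupComparison("fisher", float(odds), float(p))
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return GroupComparison("chi2", float(chi2), float(p))

    def _normalish(x: np.ndarray) -> bool:
        if len(x) < 20:
            return False
        return stats.normaltest(x).pvalue > 0.05

    if _normalish(g0) and _normalish(g1):
        t, p = stats.ttest_ind(g0, g1)
        return GroupComparison("t", float(t), float(p))
    u, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
    return GroupComparison("mannwhitney", float(u), float(p))


# ---------------------------------------------------------------------------
# Design-matrix construction


def build_design(
    df: pd.DataFrame,
    terms: list[str],
    add_intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix with reference-coded categorical expansion.

    Categorical columns (object/categorical dtype or names listed in
    ``CATEGORICAL_COVARIATES`` with non-numeric content) are expanded to
    indicators, dropping the most frequent level as reference.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(df)))
        names.append("(intercept)")
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"term {term!r} not in cohort frame")
        s = df[term]
        if s.dtype == bool:
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            counts = s.value_counts()
            ref = counts.index[0]
            for level in counts.index[1:]:
                cols.append((s == level).to_numpy(dtype=float))
                names.append(f"{term}[{level}]")
        else:
            arr = s.to_numpy(dtype=float)
            if np.isnan(arr).any():
                raise ValueError(f"term {term!r} contains missing values")
            cols.append(arr)
            names.append(term)
    X = np.column_stack(cols)
    return X, names


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily keep a maximal linearly independent set of columns."""
    n, p = X.shape
    # scale for a stable rank decision
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Q: list[np.ndarray] = []
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(p):
        v = X[:, j] / norms[j]
        for q in Q:
            v = v - (q @ v) * q
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            Q.append(v / nv)
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        logger.warning("dropping aliased design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep], dropped


# ---------------------------------------------------------------------------
# Logistic solver


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable sum(y*eta - log(1+exp(eta)))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _penalized_loglik(y: np.ndarray, eta: np.ndarray, X: np.ndarray) -> float:
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _loglik(y, eta) + 0.5 * logdet


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    method: str = "ml",
    term_names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    allow_separation: bool = False,
    offset: np.ndarray | None = None,
) -> LogisticFit:
    """Fit a binary logistic model by Newton iteration.

    Parameters
    ----------
    X
        Design matrix including any intercept column (see
        :func:`build_design`), or a DataFrame whose columns name the terms.
    y
        Binary outcome (0/1).
    method
        ``"ml"`` for plain maximum likelihood; ``"firth"`` for the
        Jeffreys-prior score modification, where the score becomes
        ``X' (y - mu + h (1/2 - mu))`` with ``h`` the hat-matrix diagonal.
    allow_separation
        Under ML, divergence due to separation normally raises
        :class:`SeparationError`; with ``allow_separation=True`` the fit is
        returned with ``separation_detected=True`` instead.

    Aliased (linearly dependent) design columns are dropped and reported
    on the fit. Convergence criterion: (modified) score norm below ``tol``.
    """
    method = method.lower()
    if method not in ("ml", "firth"):
        raise ValueError(f"unknown method {method!r}")
    if isinstance(X, pd.DataFrame):
        term_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if term_names is None:
        term_names = [f"x{j}" for j in range(X.shape[1])]
    X, names, dropped = _drop_aliased(X, list(term_names))
    n, p = X.shape
    firth = method == "firth"
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p)
    objective = _penalized_loglik if firth else (lambda yy, ee, XX: _loglik(yy, ee))
    eta = X @ beta + off
    obj = objective(y, eta, X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = (X.T * w) @ X
        if firth:
            try:
                sol = np.linalg.solve(info, X.T)
            except np.linalg.LinAlgError:
                sol = np.linalg.pinv(info) @ X.T
            h = w * np.einsum("ij,ji->i", X, sol)
            score = X.T @ (y - mu + h * (0.5 - mu))
        else:
            score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving on the (penalized) log-likelihood
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            cand_eta = X @ cand + off
            cand_obj = objective(y, cand_eta, X)
            if cand_obj >= obj - 1e-12:
                break
            step *= 0.5
        beta, eta, obj = cand, cand_eta, cand_obj

    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)

    separation = False
    if not firth:
        # Complete separation: every observation perfectly predicted (the
        # ML optimum is at infinity).  Quasi-separation: an individual
        # coefficient diverging (e.g. a rare category with no events);
        # the fit is still returned, flagged, so callers can refit with
        # Firth where the affected term matters.
        perfect = bool(np.all(mu[y == 1] > 1 - 1e-6) and np.all(mu[y == 0] < 1e-6)) if n else False
        diverged = bool(np.max(np.abs(beta)) > 15.0)
        separation = perfect or diverged
        fatal = perfect or (diverged and not converged)
        if fatal and not allow_separation:
            raise SeparationError(
                "maximum-likelihood estimates diverged ((quasi-)separation detected); "
                "refit with method='firth' for finite penalized estimates"
            )

    return LogisticFit(
        terms=names,
        beta=beta,
        cov=cov,
        method="Firth" if firth else "ML",
        converged=converged,
        iterations=it,
        loglik=obj,
        separation_detected=separation,
        dropped_terms=dropped,
        n_obs=n,
        n_events=int(y.sum()),
    )


def profile_ci(
    X: np.ndarray,
    y: np.ndarray,
    fit: LogisticFit,
    term: str,
    level: float = 0.95,
    tol: float = 1e-5,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one coefficient.

    Inverts the likelihood-ratio test: the bound on each side is the
    value ``b`` at which twice the drop of the profile log-likelihood
    (the likelihood maximized over all other coefficients with the term
    fixed at ``b``, via an offset fit) equals the chi-square(1) quantile.
    Better calibrated than the Wald interval when the model carries many
    nuisance parameters or the likelihood is asymmetric.  The design
    ``X`` must be the matrix the fit was produced from (columns in
    ``fit.terms`` order after aliased-column dropping).
    """
    j = fit.terms.index(term)
    keep = [k for k in range(len(fit.terms)) if k != j]
    Xj = X[:, j]
    Xrest = X[:, keep]
    rest_names = [fit.terms[k] for k in keep]
    crit = stats.chi2.ppf(level, df=1)
    l_hat = fit.loglik
    firth = fit.method.lower() == "firth"

    def drop(b: float) -> float:
        sub = fit_logistic(
            Xrest, y, method=fit.method.lower(), term_names=rest_names,
            offset=b * Xj, allow_separation=True,
        )
        if firth:
            # include the fixed term's contribution to the penalty scale:
            # compare on the same penalized objective as the full fit
            eta = Xrest @ sub.beta + b * Xj
            mu = expit(eta)
            w = mu * (1 - mu)
            info = (X.T * w) @ X
            sign, logdet = np.linalg.slogdet(info)
            ll = _loglik(y, eta) + 0.5 * logdet
        else:
            ll = sub.loglik
        return 2.0 * (l_hat - ll)

    b_hat = fit.beta[j]
    se = max(fit.se[j], 1e-3)

    def bound(direction: float) -> float:
        step = se
        lo, hi = b_hat, b_hat + direction * step
        # expand until the LR statistic crosses the critical value
        for _ in range(60):
            if drop(hi) >= crit:
                break
            lo, hi = hi, hi + direction * step
            step *= 1.6
        else:
            return float(direction * np.inf)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if drop(mid) < crit:
                lo = mid
            else:
                hi = mid
            if abs(hi - lo) < tol:
                break
        return 0.5 * (lo + hi)

    return float(bound(-1.0)), float(bound(+1.0))


def bootstrap_ci(
    X: np.ndarray,
    y: np.ndarray,
    term_index: int,
    method: str = "ml",
    n_boot: int = 199,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for one log-odds coefficient.

    Resamples subjects with replacement and refits the full model per
    replicate.  Unlike the Wald or profile intervals, the bootstrap
    tracks the *realized* sampling dispersion of the estimator, which
    with many adjustment covariates exceeds the inverse-information
    approximation at moderate events-per-variable.  Degenerate resamples
    (separation, singular designs) are skipped.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    draws = []
    attempts = 0
    while len(draws) < n_boot and attempts < 3 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            fit = fit_logistic(
                X[idx], y[idx], method=method, allow_separation=True
            )
        except (np.linalg.LinAlgError, ValueError):
            continue
        if fit.dropped_terms:
            continue
        draws.append(fit.beta[term_index])
    if len(draws) < max(50, n_boot // 2):
        raise RuntimeError("too many degenerate bootstrap resamples")
    alpha = (1.0 - level) / 2.0
    return (
        float(np.percentile(draws, 100 * alpha)),
        float(np.percentile(draws, 100 * (1 - alpha))),
    )


# ---------------------------------------------------------------------------
# Adjusted effects and interaction scans


def _resolve_covariates(covariates) -> list[str]:
    if covariates is None:
        return list(DEFAULT_COVARIATES)
    return list(covariates)


def adjusted_effect(
    df: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: list[str] | None = None,
    method: str = "ml",
    per_unit_decrease: bool = False,
    ci_method: str = "wald",
) -> tuple[EffectEstimate, LogisticFit]:
    """Covariate-adjusted odds ratio of ``exposure`` on ``outcome``.

    Rows where the outcome is missing (e.g. ineligible for a
    period-specific recovery flag, or lost to follow-up) are dropped.
    ``per_unit_decrease=True`` reports a continuous exposure per 1 unit
    decrease by negating the fitted coefficient.  ``ci_method`` selects
    the reporting interval: ``"wald"`` (default, matching the OR/CI
    reporting style) or ``"profile"`` (likelihood-ratio inversion,
    better calibrated under many nuisance covariates).
    """
    covs = [c for c in _resolve_covariates(covariates) if c != exposure]
    data = df.dropna(subset=[outcome])
    y = data[outcome].to_numpy(dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError(
            f"outcome {outcome!r} has fewer than 2 events or non-events; "
            "consider the Firth subgroup path"
        )
    X, names = build_design(data, [exposure] + covs)
    fit = fit_logistic(X, y, method=method, term_names=names)
    if fit.separation_detected and abs(fit.beta[fit.terms.index(exposure)]) > 15.0:
        raise SeparationError(
            f"exposure {exposure!r} is (quasi-)separated from {outcome!r}; "
            "refit with method='firth'"
        )
    note = f"per 1 unit decrease in {exposure}" if per_unit_decrease else exposure
    est = fit.term_effect(exposure, invert=per_unit_decrease, scale_note=note)
    if ci_method in ("profile", "bootstrap"):
        X_kept = X[:, [names.index(t) for t in fit.terms]]
        if ci_method == "profile":
            lo, hi = profile_ci(X_kept, y, fit, exposure)
        else:
            lo, hi = bootstrap_ci(
                X_kept, y, fit.terms.index(exposure), method=method
            )
        if per_unit_decrease:
            lo, hi = -hi, -lo
        est = EffectEstimate(
            or_point=min(max(est.or_point, float(np.exp(lo))), float(np.exp(hi))),
            ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)),
            p=est.p,
            scale_note=est.scale_note,
        )
    elif ci_method != "wald":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return est, fit


#: Firth trigger: events or non-events below this count in any
#: exposure-by-modifier stratum switches the subgroup model to Firth.
FIRTH_STRATUM_MIN = 8


def _needs_firth(data: pd.DataFrame, exposure: str, modifier: str, outcome: str) -> bool:
    y = data[outcome].to_numpy(dtype=float)
    for e in (0, 1):
        for m in (0, 1):
            sel = (data[exposure].to_numpy(dtype=float) == e) & (
                data[modifier].to_numpy(dtype=float) == m
            )
            if sel.sum() == 0:
                return True
            events = y[sel].sum()
            if events < FIRTH_STRATUM_MIN or (sel.sum() - events) < FIRTH_STRATUM_MIN:
                return True
    return False


@dataclass
class InteractionResult:
    modifier: str
    or_modifier_absent: float
    or_modifier_present: float
    p_interaction: float
    method: str
    fit: LogisticFit


def interaction_scan(
    df: pd.DataFrame,
    exposure: str,
    outcome: str,
    modifiers: list[str],
    covariates: list[str] | None = None,
) -> list[InteractionResult]:
    """Effect-modification scan over binary modifiers.

    Per modifier: one model with exposure, modifier, their product and the
    covariates; stratum-specific exposure ORs from the fitted
    coefficients; p-for-interaction from the Wald test on the product
    term.  The Firth penalty is substituted when any exposure-by-modifier
    stratum has fewer than ``FIRTH_STRATUM_MIN`` events or non-events, or
    when ML detects separation.  No multiple-comparison correction is
    applied.
    """
    covs = [c for c in _resolve_covariates(covariates) if c not in (exposure, outcome)]
    results: list[InteractionResult] = []
    for modifier in modifiers:
        data = df.dropna(subset=[outcome, modifier])
        mvals = data[modifier].to_numpy(dtype=float)
        if len(np.unique(mvals)) < 2:
            logger.warning("modifier %s constant in cohort; skipped", modifier)
            continue
        y = data[outcome].to_numpy(dtype=float)
        use_covs = [c for c in covs if c != modifier]
        X, names = build_design(data, [exposure, modifier] + use_covs)
        prod = data[exposure].to_numpy(dtype=float) * mvals
        X = np.column_stack([X, prod])
        names = names + [f"{exposure}:{modifier}"]
        method = "firth" if _needs_firth(data, exposure, modifier, outcome) else "ml"
        try:
            fit = fit_logistic(X, y, method=method, term_names=names)
            if fit.separation_detected:
                raise SeparationError("quasi-separation in interaction model")
        except SeparationError:
            method = "firth"
            fit = fit_logistic(X, y, method=method, term_names=names)
        b_exp = fit.beta[fit.terms.index(exposure)]
        b_int = fit.beta[fit.terms.index(f"{exposure}:{modifier}")]
        wald = fit.wald()
        p_int = float(wald.loc[wald["term"] == f"{exposure}:{modifier}", "p"].iloc[0])
        results.append(
            InteractionResult(
                modifier=modifier,
                or_modifier_absent=float(np.exp(b_exp)),
                or_modifier_present=float(np.exp(b_exp + b_int)),
                p_interaction=p_int,
                method=fit.method,
                fit=fit,
            )
        )
    return results
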