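"""Internal validation of a diagnostic probability model.

Implements the standard apparatus for a clinical prediction model:
discrimination (ROC curve and concordance/AUC with a bootstrap CI), threshold
selection (Youden's J), confusion-matrix metrics, the Brier score, calibration
intercept and slope with Harrell-style bootstrap optimism correction, and a
calibration belt — a likelihood-ratio confidence region around a polynomial
logistic recalibration curve, with an associated test of deviation from the
identity line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2
from sklearn.metrics import roc_auc_score, roc_curve


class ValidationError(ValueError):
    """Invalid input to a validation routine."""


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValidationError("both outcome classes must be present")


def roc_and_auc(
    probabilities,
    labels,
    *,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> ROCResult:
    """ROC curve and concordance AUC with a percentile-bootstrap CI.

    The AUC is the probability that a random diseased subject scores higher
    than a random healthy one, ties counted one half (equivalently the
    trapezoidal area under the empirical ROC).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    _check_two_classes(y)
    fpr, tpr, thr = roc_curve(y, p)
    auc = float(roc_auc_score(y, p))
    lo = hi = auc
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = y.size
        aucs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue  # degenerate resample carries no information
            aucs.append(roc_auc_score(yb, p[idx]))
        lo, hi = (float(q) for q in np.percentile(aucs, [2.5, 97.5]))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, ci_low=lo, ci_high=hi)


def optimal_cutoff(probabilities, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the observed scores; a subject is called positive
    when its score is >= the threshold. Ties in J break toward the higher
    cutoff.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    _check_two_classes(y)
    candidates = np.unique(p)
    pos = np.sort(p[y == 1])
    neg = np.sort(p[y == 0])
    sens = 1.0 - np.searchsorted(pos, candidates, side="left") / pos.size
    spec = np.searchsorted(neg, candidates, side="left") / neg.size
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]  # highest cutoff among ties
    return float(candidates[best])


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "ConfusionCounts":
        """Read counts from a one-row CSV with columns TP, FN, TN, FP."""
        row = pd.read_csv(path).iloc[0]
        cols = {c.lower(): c for c in row.index}
        try:
            return cls(*(int(row[cols[k]]) for k in ("tp", "fn", "tn", "fp")))
        except KeyError as exc:
            raise ValidationError(
                "confusion CSV must have columns TP, FN, TN, FP"
            ) from exc

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y == 1) & (yp == 1)).sum()),
            fn=int(((y == 1) & (yp == 0)).sum()),
            tn=int(((y == 0) & (yp == 0)).sum()),
            fp=int(((y == 0) & (yp == 1)).sum()),
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def confusion_metrics(counts: ConfusionCounts) -> tuple[dict, dict]:
    """Sensitivity, specificity, PPV, NPV and accuracy in percent.

    Returns ``(full_precision, whole_percent)`` dicts; a metric with a zero
    denominator is reported as None (undefined), never as 0.
    """
    c = counts
    denominators = {
        "sensitivity": c.tp + c.fn,
        "specificity": c.tn + c.fp,
        "ppv": c.tp + c.fp,
        "npv": c.tn + c.fn,
        "accuracy": c.tp + c.fn + c.tn + c.fp,
    }
    numerators = {
        "sensitivity": c.tp,
        "specificity": c.tn,
        "ppv": c.tp,
        "npv": c.tn,
        "accuracy": c.tp + c.tn,
    }
    full = {
        k: (100.0 * numerators[k] / d if d > 0 else None)
        for k, d in denominators.items()
    }
    rounded = {k: (_round_half_up(v) if v is not None else None) for k, v in full.items()}
    return full, rounded


def brier_score(probabilities, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


# ---------------------------------------------------------------------------
# Calibration intercept / slope and bootstrap optimism correction
# ---------------------------------------------------------------------------


def calibration_intercept_slope(linear_predictor, labels) -> tuple[float, float]:
    """Logistic-recalibration intercept and slope.

    Slope is the coefficient of the linear predictor in a logistic regression
    of the outcome on it; the intercept comes from an intercept-only logistic
    model with the linear predictor as offset. A model evaluated on its own
    development data gives (0, 1) exactly.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(labels, dtype=float)
    _check_two_classes(y)
    if np.ptp(lp) == 0:
        raise ValidationError("constant linear predictor; calibration slope undefined")
    fam = sm.families.Binomial()
    slope_fit = sm.GLM(y, sm.add_constant(lp), family=fam).fit()
    int_fit = sm.GLM(y, np.ones((y.size, 1)), family=fam, offset=lp).fit()
    return float(int_fit.params[0]), float(slope_fit.params[1])


@dataclass(frozen=True)
class BootstrapResult:
    """Apparent vs optimism-corrected performance (intercept, slope, brier, auc)."""

    apparent: Mapping[str, float]
    optimism: Mapping[str, float]
    corrected: Mapping[str, float]
    n_resamples: int
    n_failed: int


def bootstrap_validate(
    subjects: pd.DataFrame,
    fit_fn: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    *,
    outcome: str = "diagnosis",
    B: int = 300,
    seed: int = 0,
    max_failure_rate: float = 0.05,
) -> BootstrapResult:
    """Harrell bootstrap optimism correction of calibration and accuracy.

    ``fit_fn(df)`` must run the *full* development procedure on ``df`` and
    return a function mapping any subjects table to its linear predictor.
    For each of ``B`` resamples the procedure is refitted, performance is
    measured on the resample and on the original data, and the mean
    difference (the optimism) is subtracted from the apparent performance.
    Resamples where the fit fails (e.g. separation) are skipped; more than
    ``max_failure_rate`` failures aborts with a diagnostic.
    """
    y = subjects[outcome].to_numpy(dtype=float)
    _check_two_classes(y)

    def performance(lp: np.ndarray, yy: np.ndarray) -> dict:
        try:
            a, b = calibration_intercept_slope(lp, yy)
        except Exception:
            # degenerate (e.g. constant) predictor: slope carries no information
            a = b = float("nan")
        p = expit(lp)
        return {
            "calibration_intercept": a,
            "calibration_slope": b,
            "brier": brier_score(p, yy),
            "auc": float(roc_auc_score(yy, p)),
        }

    lp_full = fit_fn(subjects)
    apparent = performance(lp_full(subjects), y)

    rng = np.random.default_rng(seed)
    n = len(subjects)
    sums = {k: 0.0 for k in apparent}
    counts = {k: 0 for k in apparent}
    done = failed = 0
    while done + failed < B:
        idx = rng.integers(0, n, n)
        boot = subjects.iloc[idx].reset_index(drop=True)
        yb = boot[outcome].to_numpy(dtype=float)
        if yb.min() == yb.max():
            failed += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # resample refits may be fragile
                lp_boot = fit_fn(boot)
                perf_boot = performance(lp_boot(boot), yb)
                perf_test = performance(lp_boot(subjects), y)
        except Exception:
            failed += 1
            continue
        for k in sums:
            d = perf_boot[k] - perf_test[k]
            if np.isfinite(d):
                sums[k] += d
                counts[k] += 1
        done += 1
    if failed > max_failure_rate * B:
        raise ValidationError(
            f"model development failed on {failed}/{B} bootstrap resamples; "
            "systematic separation suspected"
        )
    optimism = {
        k: (sums[k] / counts[k] if counts[k] else float("nan")) for k in sums
    }
    corrected = {k: apparent[k] - optimism[k] for k in apparent}
    return BootstrapResult(
        apparent=apparent,
        optimism=optimism,
        corrected=corrected,
        n_resamples=done,
        n_failed=failed,
    )


# ---------------------------------------------------------------------------
# Calibration belt
# ---------------------------------------------------------------------------


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass(frozen=True)
class CalibrationBelt:
    """Polynomial logistic recalibration curve with likelihood-ratio bands."""

    degree: int
    p_value: float
    grid_prob: np.ndarray  # predicted-probability grid
    fitted_prob: np.ndarray  # recalibration curve on the grid
    bands: Mapping[float, tuple[np.ndarray, np.ndarray]]  # conf -> (lower, upper)

    def covers_identity(self, confidence: float) -> np.ndarray:
        lo, hi = self.bands[confidence]
        return (self.grid_prob >= lo) & (self.grid_prob <= hi)


def calibration_belt(
    probabilities,
    labels,
    *,
    confidence_levels: Sequence[float] = (0.80, 0.95),
    max_degree: int = 4,
    forward_alpha: float = 0.05,
    n_grid: int = 50,
    compute_bands: bool = True,
) -> CalibrationBelt:
    """Calibration belt: degree-selected polynomial logit recalibration.

    The outcome is regressed on a polynomial in ``logit(probability)``; the
    degree starts at 1 and grows while the likelihood-ratio test for the next
    term is significant at ``forward_alpha`` (capped at ``max_degree``). The
    deviation test compares the selected curve against the identity line
    (perfect calibration) with a likelihood-ratio test on the number of fitted
    coefficients. The belt itself inverts the likelihood-ratio confidence
    region pointwise at each confidence level.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size != y.size:
        raise ValidationError("probabilities and labels differ in length")
    if p.size < 40:
        raise ValidationError("calibration belt needs n >= 40")
    _check_two_classes(y)
    if np.ptp(p) == 0:
        raise ValidationError("degenerate probabilities (all equal)")
    p = np.clip(p, 1e-10, 1 - 1e-10)
    ge = logit(p)
    mu, sd = float(ge.mean()), float(ge.std())
    z = (ge - mu) / sd  # standardized basis keeps high degrees well conditioned

    def design(m: int) -> np.ndarray:
        return np.vander(z, m + 1, increasing=True)

    def fit(m: int):
        res = sm.GLM(y, design(m), family=sm.families.Binomial()).fit()
        return res.params, float(res.llf)

    params, ll = fit(1)
    degree = 1
    while degree < max_degree:
        params_next, ll_next = fit(degree + 1)
        lr = 2.0 * (ll_next - ll)
        if chi2.sf(lr, 1) < forward_alpha:
            degree += 1
            params, ll = params_next, ll_next
        else:
            break

    ll_identity = _loglik(ge, y)
    deviance = max(2.0 * (ll - ll_identity), 0.0)
    p_value = float(chi2.sf(deviance, degree + 1))

    grid_prob = np.linspace(
        float(np.quantile(p, 0.02)), float(np.quantile(p, 0.98)), n_grid
    )
    zg = (logit(grid_prob) - mu) / sd
    Xg = np.vander(zg, degree + 1, increasing=True)
    fitted_prob = expit(Xg @ params)

    bands: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    if compute_bands:
        X = design(degree)

        def neg_ll_and_grad(beta):
            eta = X @ beta
            mu_ = expit(eta)
            return -_loglik(eta, y), -(X.T @ (y - mu_))

        for conf in confidence_levels:
            q = chi2.ppf(conf, degree + 1)
            ll_floor = ll - q / 2.0
            lo = np.empty(n_grid)
            hi = np.empty(n_grid)
            constraint = {
                "type": "ineq",
                "fun": lambda b: _loglik(X @ b, y) - ll_floor,
                "jac": lambda b: X.T @ (y - expit(X @ b)),
            }
            for i in range(n_grid):
                c = Xg[i]
                for sign, store in ((1.0, hi), (-1.0, lo)):
                    res = optimize.minimize(
                        lambda b: -sign * (c @ b),
                        params,
                        jac=lambda b: -sign * c,
                        constraints=[constraint],
                        method="SLSQP",
                        options={"maxiter": 200, "ftol": 1e-8},
                    )
                    if not res.success:
                        warnings.warn(
                            f"belt bound optimization did not converge at grid {i}"
                        )
                    store[i] = c @ res.x
            bands[conf] = (expit(lo), expit(hi))

    return CalibrationBelt(
        degree=degree,
        p_value=p_value,
        grid_prob=grid_prob,
        fitted_prob=fitted_prob,
        bands=bands,
    )


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    """Everything internal validation produces for one model on one cohort."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    counts: ConfusionCounts
    metrics: Mapping[str, float | None]
    metrics_pct: Mapping[str, int | None]
    brier: float
    calibration_intercept: float
    calibration_slope: float
    corrected: Mapping[str, float]
    belt_p_value: float
    belt_degree: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "cutoff": self.cutoff,
            "confusion": {
                "TP": self.counts.tp,
                "FN": self.counts.fn,
                "TN": self.counts.tn,
                "FP": self.counts.fp,
            },
            "metrics": dict(self.metrics),
            "metrics_pct": dict(self.metrics_pct),
            "brier": self.brier,
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
            "bootstrap_corrected": dict(self.corrected),
            "calibration_belt": {
                "p_value": self.belt_p_value,
                "degree": self.belt_degree,
            },
        }


def validate_model(
    subjects: pd.DataFrame,
    linear_predictor: np.ndarray,
    *,
    outcome: str = "diagnosis",
    cutoff: float | None = None,
    fit_fn: Callable | None = None,
    B: int = 300,
    seed: int = 0,
    n_boot_auc: int = 2000,
) -> ValidationReport:
    """Assemble the full internal-validation report for one model.

    ``linear_predictor`` are the model's logits on ``subjects``. If ``cutoff``
    is None the Youden-optimal threshold is derived from the data. Optimism
    correction runs only when ``fit_fn`` (the full development procedure) is
    supplied; otherwise the corrected block repeats the apparent values.
    """
    y = subjects[outcome].to_numpy(dtype=float)
    lp = np.asarray(linear_predictor, dtype=float)
    probs = expit(lp)
    roc = roc_and_auc(probs, y, n_boot=n_boot_auc, seed=seed)
    cut = float(cutoff) if cutoff is not None else optimal_cutoff(probs, y)
    counts = ConfusionCounts.from_predictions(y, probs >= cut)
    full, pct = confusion_metrics(counts)
    a, b = calibration_intercept_slope(lp, y)
    if fit_fn is not None:
        boot = bootstrap_validate(subjects, fit_fn, outcome=outcome, B=B, seed=seed)
        corrected = dict(boot.corrected)
    else:
        corrected = {
            "calibration_intercept": a,
            "calibration_slope": b,
            "brier": brier_score(probs, y),
            "auc": roc.auc,
        }
    if y.size >= 40:
        belt = calibration_belt(probs, y, compute_bands=False)
        belt_p, belt_degree = belt.p_value, belt.degree
    else:
        belt_p, belt_degree = float("nan"), 0  # belt needs n >= 40
    return ValidationReport(
        auc=roc.auc,
        auc_ci=(roc.ci_low, roc.ci_high),
        cutoff=cut,
        counts=counts,
        metrics=full,
        metrics_pct=pct,
        brier=brier_score(probs, y),
        calibration_intercept=a,
        calibration_slope=b,
        corrected=corrected,
        belt_p_value=belt_p,
        belt_degree=belt_degree,
    )
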