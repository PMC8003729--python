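"""Logistic prediction model for Raynaud's phenomenon from rewarming features.

The diagnostic model is an ordinary logistic regression on subject-level
rewarming characteristics. Development follows standard clinical
prediction-model practice: a Pearson correlation screen drops one of each pair
of highly collinear candidates, and backward elimination removes predictors by
Wald p-value until all remaining terms are significant. The published model
uses two predictors,

    logit p(RP) = 2.4 + 0.11 * time_to_t_end [min] - 0.30 * t_base [°C],

with decision threshold p >= 0.46, and is available ready-made through
:func:`published_model`. The same model can be presented as a nomogram
(linear point scales per predictor, total points mapped to probability through
the logistic link).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .validation import optimal_cutoff

POSITIVE = "positive"
NEGATIVE = "negative"

#: Default candidate predictors screened during model development. Gender is
#: deliberately absent (too few male patients to support it); age is screened
#: but does not survive elimination on typical cohorts.
DEFAULT_CANDIDATES = [
    "time_to_t_end",
    "t_base",
    "t_0",
    "t_end",
    "t_50_star",
    "R_pct",
    "curve_type",
    "age",
]


class ModelError(ValueError):
    """Model development failed."""


class SeparationError(ModelError):
    """Perfect separation: the MLE does not exist."""


class ConvergenceError(ModelError):
    """The likelihood maximization did not converge."""


@dataclass(frozen=True)
class PredictionModel:
    """A fitted (or published) logistic diagnostic model.

    ``coefficients`` maps predictor name to log-odds slope; ``cutoff`` is the
    probability threshold at or above which the diagnosis is called positive.
    """

    intercept: float
    coefficients: Mapping[str, float]
    cutoff: float = 0.46
    provenance: str = "refit"  # "published" or "refit"

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ModelError("cutoff must lie in (0, 1)")
        object.__setattr__(
            self, "coefficients", MappingProxyType(dict(self.coefficients))
        )

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, data: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            lp = np.full(len(data), self.intercept, dtype=float)
            for name, beta in self.coefficients.items():
                lp += beta * data[name].to_numpy(dtype=float)
            return lp
        lp = self.intercept
        for name, beta in self.coefficients.items():
            lp += beta * float(data[name])
        return np.float64(lp)

    def predict_probability(self, data) -> np.ndarray:
        return expit(self.linear_predictor(data))

    def classify(self, probability) -> np.ndarray | str:
        """Positive iff probability >= cutoff (the boundary counts positive)."""
        p = np.asarray(probability, dtype=float)
        out = np.where(p >= self.cutoff, POSITIVE, NEGATIVE)
        return out.item() if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "cutoff": float(self.cutoff),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionModel":
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            cutoff=d.get("cutoff", 0.46),
            provenance=d.get("provenance", "refit"),
        )


def published_model() -> PredictionModel:
    """The published two-predictor model with its decision threshold."""
    return PredictionModel(
        intercept=2.4,
        coefficients={"time_to_t_end": 0.11, "t_base": -0.30},
        cutoff=0.46,
        provenance="published",
    )


def predict_probability(
    model: PredictionModel, time_to_t_end: float, t_base: float
) -> float:
    """Probability of RP for the two-predictor model (time in minutes, °C)."""
    return float(
        model.predict_probability({"time_to_t_end": time_to_t_end, "t_base": t_base})
    )


def classify(model: PredictionModel, probability: float) -> str:
    return model.classify(probability)


# ---------------------------------------------------------------------------
# Predictor screening
# ---------------------------------------------------------------------------


def correlation_screen(
    data: pd.DataFrame,
    *,
    threshold: float = 0.75,
    priority: Sequence[str] | None = None,
) -> list[str]:
    """Drop one of each pair of highly correlated candidate predictors.

    For every pair with Pearson ``|r| > threshold`` the member appearing later
    in ``priority`` (default: the column order of ``data``) is dropped. The
    retained names come back in the original column order.
    """
    cols = list(data.columns)
    if len(cols) < 2:
        raise ModelError("need at least 2 candidate predictors to screen")
    values = data.to_numpy(dtype=float)
    if np.any(values.std(axis=0) == 0):
        bad = [c for c, s in zip(cols, values.std(axis=0)) if s == 0]
        raise ModelError(f"constant column(s) {bad}: correlation undefined")
    corr = data.corr(method="pearson")
    priority = list(priority) if priority is not None else cols
    rank = {c: priority.index(c) if c in priority else len(priority) + i
            for i, c in enumerate(cols)}
    dropped: set[str] = set()
    for a in sorted(cols, key=rank.get):
        if a in dropped:
            continue
        for b in sorted(cols, key=rank.get):
            if b == a or b in dropped:
                continue
            if abs(corr.loc[a, b]) > threshold:
                dropped.add(b if rank[b] > rank[a] else a)
    return [c for c in cols if c not in dropped]


# ---------------------------------------------------------------------------
# Backward-elimination logistic estimator
# ---------------------------------------------------------------------------


class BackwardEliminationLogit(BaseEstimator, ClassifierMixin):
    """Logistic classifier developed by correlation screen + backward elimination.

    Maximum-likelihood logistic regression (with intercept) is fitted on the
    candidate predictors; the predictor with the largest Wald p-value is
    removed and the model refitted until every remaining predictor has
    ``p < p_stay``. The decision threshold is either a fixed probability or
    derived from the training ROC curve by maximizing Youden's J.

    Parameters
    ----------
    p_stay : float
        Wald significance level a predictor must reach to stay.
    screen : bool
        Apply the Pearson correlation screen before elimination.
    screen_threshold : float
        |r| above which one of a predictor pair is dropped.
    priority : sequence of str, optional
        Preference order used by the screen; defaults to column order.
    cutoff : "youden" or float
        Decision threshold policy.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_selected,)
    selected_features_ : list of str
    pvalues_, bse_, wald_z_ : pd.Series indexed like the final model terms
    cutoff_ : float
    elimination_trace_ : list of (dropped name, its Wald p at removal)
    """

    def __init__(
        self,
        p_stay: float = 0.05,
        screen: bool = True,
        screen_threshold: float = 0.75,
        priority: Sequence[str] | None = None,
        cutoff: str | float = "youden",
        max_iter: int = 200,
        on_separation: str = "error",
    ) -> None:
        self.p_stay = p_stay
        self.screen = screen
        self.screen_threshold = screen_threshold
        self.priority = priority
        self.cutoff = cutoff
        self.max_iter = max_iter
        self.on_separation = on_separation

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def _drop_aliased(self, Xf: pd.DataFrame, cols: list[str]) -> list[str]:
        """Greedily drop columns that are (near-)linear combinations of the
        columns before them, priority order first — the pairwise screen cannot
        catch exact multi-way dependences such as a derived average."""
        priority = list(self.priority) if self.priority is not None else cols
        rank = {c: priority.index(c) if c in priority else len(priority) + i
                for i, c in enumerate(cols)}
        ordered = sorted(cols, key=rank.get)
        design = np.column_stack([np.ones(len(Xf))])
        kept: list[str] = []
        for c in ordered:
            candidate = np.column_stack([design, Xf[c].to_numpy(float)])
            if np.linalg.matrix_rank(candidate) > np.linalg.matrix_rank(design):
                design = candidate
                kept.append(c)
            else:
                warnings.warn(f"dropping aliased predictor {c!r}")
        return [c for c in cols if c in kept]

    def _fit_once(self, Xf: pd.DataFrame, y: np.ndarray):
        design = sm.add_constant(Xf, has_constant="add")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=self.max_iter)
        except np.linalg.LinAlgError as exc:
            # singular Hessian along the separating direction
            raise SeparationError(
                f"singular information matrix while fitting {list(Xf.columns)}; "
                "perfect separation suspected"
            ) from exc
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            if "erfect" in type(exc).__name__ or "erfect" in str(exc):
                raise SeparationError(str(exc)) from exc
            raise
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError(
                f"logistic fit did not converge within {self.max_iter} iterations"
            )
        # Quasi-separated predictors are tolerated at this point: their Wald
        # standard errors blow up (Hauck-Donner), so backward elimination
        # prunes them on the next step. The final model is re-checked in fit().
        return res

    def fit(self, X, y):
        Xf = self._as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if Xf.shape[0] != y.size:
            raise ModelError("X and y have different lengths")
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ModelError("outcome must be binary 0/1 with both classes present")
        if y.size <= Xf.shape[1]:
            raise ModelError("need more subjects than candidate predictors")

        cols = list(Xf.columns)
        if self.screen and len(cols) >= 2:
            cols = correlation_screen(
                Xf, threshold=self.screen_threshold, priority=self.priority
            )
        cols = self._drop_aliased(Xf, cols)
        if self.on_separation not in ("error", "drop"):
            raise ModelError(f"unknown on_separation policy {self.on_separation!r}")
        trace: list[tuple[str, float]] = []
        while cols:
            try:
                res = self._fit_once(Xf[cols], y)
            except (SeparationError, ConvergenceError):
                if self.on_separation == "error":
                    raise
                # MLE does not exist (or barely): drop the strongest
                # univariate separator and keep going
                r = {c: abs(np.corrcoef(Xf[c], y)[0, 1]) for c in cols}
                worst = max(r, key=r.get)
                trace.append((worst, float("nan")))
                cols = [c for c in cols if c != worst]
                continue
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] < self.p_stay:
                final = res.params[cols].abs()
                if res.bse.isna().any() or final.max() > 50:
                    offender = str(final.idxmax())
                    if self.on_separation == "error":
                        raise SeparationError(
                            f"final model is separated along predictor "
                            f"{offender!r} (|coef| = {final.max():.1f} logits)"
                        )
                    trace.append((offender, float("nan")))
                    cols = [c for c in cols if c != offender]
                    continue
                break
            trace.append((worst, float(pvals[worst])))
            cols = [c for c in cols if c != worst]
        else:
            # every predictor eliminated: intercept-only model
            ones = pd.DataFrame({"const": np.ones(y.size)})
            res = sm.Logit(y, ones).fit(disp=0)
            self.result_ = res
            self.selected_features_ = []
            self.intercept_ = float(res.params["const"])
            self.coef_ = np.empty(0)
            self.pvalues_ = pd.Series(dtype=float)
            self.bse_ = pd.Series(dtype=float)
            self.wald_z_ = pd.Series(dtype=float)
            self.elimination_trace_ = trace
            self.classes_ = np.array([0, 1])
            self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
            self.cutoff_ = self.cutoff if isinstance(self.cutoff, float) else 0.5
            return self

        self.result_ = res
        self.selected_features_ = cols
        self.intercept_ = float(res.params["const"])
        self.coef_ = res.params[cols].to_numpy()
        self.bse_ = res.bse[cols]
        self.pvalues_ = res.pvalues[cols]
        self.wald_z_ = res.tvalues[cols]
        self.elimination_trace_ = trace
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        if isinstance(self.cutoff, str):
            if self.cutoff != "youden":
                raise ModelError(f"unknown cutoff policy {self.cutoff!r}")
            p_train = self.predict_proba(Xf)[:, 1]
            self.cutoff_ = optimal_cutoff(p_train, y)
        else:
            self.cutoff_ = float(self.cutoff)
        return self

    def decision_function(self, X) -> np.ndarray:
        Xf = self._as_frame(X)
        lp = np.full(len(Xf), self.intercept_, dtype=float)
        for name, beta in zip(self.selected_features_, self.coef_):
            lp += beta * Xf[name].to_numpy(dtype=float)
        return lp

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.cutoff_).astype(int)

    def summary_frame(self) -> pd.DataFrame:
        """Per-term estimates, SEs, Wald z and z², and p-values of the final model."""
        terms = ["const"] + self.selected_features_
        res = self.result_
        return pd.DataFrame(
            {
                "estimate": res.params[terms],
                "std_error": res.bse[terms],
                "wald_z": res.tvalues[terms],
                "wald_chi2": res.tvalues[terms] ** 2,
                "p_value": res.pvalues[terms],
            }
        )

    def to_prediction_model(self) -> PredictionModel:
        return PredictionModel(
            intercept=self.intercept_,
            coefficients=dict(zip(self.selected_features_, self.coef_)),
            cutoff=float(np.clip(self.cutoff_, 1e-6, 1 - 1e-6)),
            provenance="refit",
        )


def fit_logistic(
    subjects: pd.DataFrame,
    candidates: Sequence[str] = tuple(DEFAULT_CANDIDATES),
    *,
    outcome: str = "diagnosis",
    p_stay: float = 0.05,
    screen: bool = True,
    screen_threshold: float = 0.75,
    cutoff: str | float = "youden",
    on_separation: str = "error",
) -> tuple[PredictionModel, pd.DataFrame]:
    """Develop a model on a subjects table; returns (model, summary table).

    ``curve_type`` columns holding string labels are recoded to a 0/1
    indicator for "horizontal" before fitting.
    """
    df = subjects.copy()
    if "curve_type" in df.columns and df["curve_type"].dtype == object:
        df["curve_type"] = (df["curve_type"] == "horizontal").astype(float)
    cand = [c for c in candidates if c in df.columns]
    if not cand:
        raise ModelError("none of the candidate predictors are present")
    est = BackwardEliminationLogit(
        p_stay=p_stay,
        screen=screen,
        screen_threshold=screen_threshold,
        priority=list(candidates),
        cutoff=cutoff,
        on_separation=on_separation,
    )
    est.fit(df[cand], df[outcome].to_numpy(dtype=float))
    return est.to_prediction_model(), est.summary_frame()


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Nomogram:
    """Linear point-scale presentation of a logistic model.

    Each predictor's points are ``scale * beta * (value - reference)`` with the
    reference chosen at the end of the observed range contributing least to
    the risk, so points are non-negative; ``scale`` is set so the widest
    predictor spans 0–100 points. Total points map to probability through the
    logistic link.
    """

    intercept: float
    coefficients: Mapping[str, float]
    ranges: Mapping[str, tuple[float, float]]
    references: Mapping[str, float]
    scale: float  # points per logit
    cutoff: float

    def points(self, name: str, value: float) -> float:
        beta = self.coefficients[name]
        return self.scale * beta * (value - self.references[name])

    def total_points(self, values: Mapping[str, float]) -> float:
        return float(sum(self.points(k, values[k]) for k in self.coefficients))

    def probability(self, total_points: float) -> float:
        base = self.intercept + sum(
            beta * self.references[k] for k, beta in self.coefficients.items()
        )
        return float(expit(base + total_points / self.scale))

    def lookup(self, values: Mapping[str, float]) -> float:
        """Probability read off the nomogram for a set of predictor values."""
        return self.probability(self.total_points(values))


def build_nomogram(
    model: PredictionModel, ranges: Mapping[str, tuple[float, float]]
) -> Nomogram:
    """Construct the point scales of a nomogram over the stated predictor ranges."""
    coefs = {}
    refs = {}
    for name, beta in model.coefficients.items():
        if name not in ranges:
            raise ModelError(f"no range stated for predictor {name!r}")
        lo, hi = ranges[name]
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ModelError(f"invalid range for {name!r}: {(lo, hi)}")
        if beta == 0.0:
            warnings.warn(f"predictor {name!r} has zero coefficient; excluded")
            continue
        coefs[name] = beta
        refs[name] = lo if beta > 0 else hi
    if not coefs:
        raise ModelError("no non-zero coefficients; nomogram undefined")
    span = max(abs(b) * (ranges[k][1] - ranges[k][0]) for k, b in coefs.items())
    scale = 100.0 / span
    return Nomogram(
        intercept=model.intercept,
        coefficients=coefs,
        ranges={k: tuple(map(float, ranges[k])) for k in coefs},
        references=refs,
        scale=scale,
        cutoff=model.cutoff,
    )


def render_nomogram(nomogram: Nomogram, path: str) -> None:
    """Draw the nomogram (point scales plus the total-points/probability axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(nomogram.coefficients)
    n_axes = len(names) + 2  # points axis + predictors + probability axis
    fig, ax = plt.subplots(figsize=(8, 1.2 * n_axes))
    ax.set_ylim(-0.5, n_axes - 0.5)
    ax.set_xlim(-5, 105)
    ax.axis("off")

    def hline(y, label):
        ax.plot([0, 100], [y, y], color="k", lw=1)
        ax.text(-4, y, label, ha="right", va="center", fontsize=9)

    y = n_axes - 1
    hline(y, "Points")
    for p in range(0, 101, 10):
        ax.plot([p, p], [y - 0.08, y + 0.08], color="k", lw=1)
        ax.text(p, y + 0.18, f"{p}", ha="center", fontsize=7)

    for name in names:
        y -= 1
        lo, hi = nomogram.ranges[name]
        hline(y, name)
        for v in np.linspace(lo, hi, 6):
            p = nomogram.points(name, v)
            ax.plot([p, p], [y - 0.08, y + 0.08], color="k", lw=1)
            ax.text(p, y + 0.18, f"{v:g}", ha="center", fontsize=7)

    y -= 1
    # total-points axis annotated with probability, cutoff marked
    max_total = sum(
        abs(nomogram.coefficients[k])
        * (nomogram.ranges[k][1] - nomogram.ranges[k][0])
        * nomogram.scale
        for k in names
    )
    hline(y, "Probability of RP")
    for tp in np.linspace(0, max_total, 9):
        x = 100 * tp / max_total
        ax.plot([x, x], [y - 0.08, y + 0.08], color="k", lw=1)
        ax.text(x, y - 0.3, f"{nomogram.probability(tp):.2f}", ha="center", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
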