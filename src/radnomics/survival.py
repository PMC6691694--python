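"""Cox modelling, Rad-scores, and survival-based validation.

The modelling surface follows the model/results convention: ``CoxPH`` is
built from a DataFrame and ``fit()`` returns a ``CoxPHResults`` carrying the
coefficient estimates, their uncertainties, the Breslow baseline cumulative
hazard, risk scores (linear predictors), survival predictions and a
``summary()`` table.  Estimation is delegated to lifelines'
``CoxPHFitter`` (Newton-Raphson on the partial likelihood; the Breslow
step-function baseline hazard at event times).

A *Rad-score* is the uncentered linear predictor beta' x of a Cox model over
selected radiomic features (Rad-score1: CET1-w, Rad-score2: T2-w) or the
combined radiomic + clinical linear combination.  The published combined
model is available as a frozen constant set (``PUBLISHED_MODEL``) and is
never re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "CoxPH",
    "CoxPHResults",
    "PublishedModel",
    "PUBLISHED_MODEL",
    "combined_rad_score",
    "concordance_index",
    "km_logrank",
    "stratify_by_median",
    "calibration_curve",
    "split_cohort",
    "baseline_table",
    "backward_eliminate",
]


# ---------------------------------------------------------------------------
# Cox proportional hazards model / results
# ---------------------------------------------------------------------------


class CoxPH:
    """Cox proportional-hazards model specification.

    Parameters
    ----------
    data : DataFrame with the duration, event and covariate columns.
    duration_col, event_col : column names of the follow-up time (months)
        and the event indicator (1 = local recurrence observed).
    covariates : list of covariate column names; default = all remaining
        numeric columns.
    """

    def __init__(self, data: pd.DataFrame, duration_col: str = "time",
                 event_col: str = "event", covariates: list[str] | None = None):
        self.duration_col = duration_col
        self.event_col = event_col
        if covariates is None:
            covariates = [
                c for c in data.columns
                if c not in (duration_col, event_col, "patient_id")
                and np.issubdtype(data[c].dtype, np.number)
            ]
        self.covariates = list(covariates)
        cols = [duration_col, event_col] + self.covariates
        self.data = data[cols].astype(float).reset_index(drop=True)
        if self.data[event_col].sum() < 1:
            raise ValueError("Cox model needs at least one observed event")
        for c in self.covariates:
            if self.data[c].nunique() < 2:
                raise ValueError(f"covariate {c!r} is constant")

    @classmethod
    def from_dataframe(cls, data, duration_col="time", event_col="event", covariates=None):
        return cls(data, duration_col, event_col, covariates)

    def fit(self, penalizer: float = 0.0) -> "CoxPHResults":
        fitter = CoxPHFitter(penalizer=penalizer)
        fitter.fit(self.data, duration_col=self.duration_col, event_col=self.event_col,
                   fit_options={"precision": 1e-9})
        return CoxPHResults(self, fitter)


class CoxPHResults:
    """Fitted Cox model: coefficients, baseline hazard, predictions."""

    def __init__(self, model: CoxPH, fitter: CoxPHFitter):
        self.model = model
        self._fitter = fitter
        self.params_ = fitter.params_.copy()
        self.standard_errors_ = fitter.standard_errors_.copy()
        self.confidence_intervals_ = fitter.confidence_intervals_.copy()
        self.log_likelihood_ = float(fitter.log_likelihood_)
        self.covariate_means_ = model.data[model.covariates].mean()
        bch = fitter.baseline_cumulative_hazard_
        self._bch_times = bch.index.to_numpy(dtype=float)
        self._bch_values = bch.iloc[:, 0].to_numpy(dtype=float)
        if not np.all(np.diff(self._bch_values) >= -1e-12):
            raise RuntimeError("baseline cumulative hazard is not nondecreasing")

    # -- inference ---------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        return self._fitter.summary

    @property
    def p_values_(self) -> pd.Series:
        return self._fitter.summary["p"]

    # -- prediction --------------------------------------------------------

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Uncentered risk score beta' x (the Rad-score of this model)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.params_.index].to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.params_.to_numpy()

    def baseline_cumulative_hazard(self, times) -> np.ndarray:
        """Breslow baseline cumulative hazard (at mean covariates) at ``times``."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self._bch_times, times, side="right") - 1
        out = np.where(idx >= 0, self._bch_values[np.clip(idx, 0, None)], 0.0)
        return out

    def predict_survival(self, X, times) -> np.ndarray:
        """S(t | x) = exp(-Lambda0(t) exp(beta'(x - xbar))).

        Returns an array of shape (n_patients, n_times).
        """
        lp = self.linear_predictor(X)
        lp_centered = lp - float(self.covariate_means_ @ self.params_)
        lam0 = self.baseline_cumulative_hazard(times)
        return np.exp(-np.outer(np.exp(lp_centered), lam0))

    def concordance_on(self, X, time, event) -> float:
        c, _ = concordance_index(self.linear_predictor(X), time, event)
        return c


# ---------------------------------------------------------------------------
# Published combined model (frozen constants, never re-estimated)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PublishedModel:
    """The printed combined-model coefficients and risk threshold."""

    coefficients: tuple = (
        ("radscore1", 0.88663),
        ("radscore2", 0.50748),
        ("gender", 0.02159),
        ("age", 0.02012),
        ("hgb", 0.00691),
        ("n_stage", -0.21954),
    )
    threshold: float = 5.50

    @property
    def coef_dict(self) -> dict:
        return dict(self.coefficients)

    def score(self, covariates: dict) -> float:
        missing = [k for k, _ in self.coefficients if k not in covariates]
        if missing:
            raise KeyError(f"missing covariates for combined Rad-score: {missing}")
        return float(sum(beta * float(covariates[k]) for k, beta in self.coefficients))

    def risk_group(self, score: float) -> str:
        return "high" if score >= self.threshold else "low"


PUBLISHED_MODEL = PublishedModel()


def combined_rad_score(radscore1, radscore2, clinical: pd.DataFrame,
                       model: PublishedModel | CoxPHResults = PUBLISHED_MODEL) -> np.ndarray:
    """Combined Rad-score over {Rad-score1, Rad-score2, gender, age, HGB, N stage}.

    With the published model the six printed coefficients are used verbatim;
    with a fitted ``CoxPHResults`` its estimated coefficients are used.
    """
    table = clinical.copy()
    table["radscore1"] = np.asarray(radscore1, dtype=float)
    table["radscore2"] = np.asarray(radscore2, dtype=float)
    if isinstance(model, PublishedModel):
        cols = [k for k, _ in model.coefficients]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise KeyError(f"missing covariates for combined Rad-score: {missing}")
        betas = np.array([b for _, b in model.coefficients])
        return table[cols].to_numpy(dtype=float) @ betas
    return model.linear_predictor(table)


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------


def concordance_index(scores, time, event) -> tuple[float, int]:
    """Harrell's C over usable pairs, with the pair count.

    A pair is usable when the ordering of failure times is determinable
    under censoring: the earlier time is an observed event, or the times tie
    with exactly one event (the event patient failed first).  A usable pair
    is concordant when the patient failing first has the higher risk score;
    tied scores contribute 0.5.  Pairs of tied event times with two events
    and pairs of two censored observations are not usable.

    Returns ``(C, n_usable_pairs)``.  Raises if no pair is usable.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("scores, time and event must have equal length")

    # matrix form: usable(i, j) means i is known to fail before j
    T_i, T_j = t[:, None], t[None, :]
    E_i, E_j = e[:, None], e[None, :]
    earlier = (T_i < T_j) & E_i
    tied_time = (T_i == T_j) & E_i & ~E_j
    usable = earlier | tied_time
    np.fill_diagonal(usable, False)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs for the concordance index")
    S_i, S_j = s[:, None], s[None, :]
    concordant = (S_i > S_j) & usable
    tied_score = (S_i == S_j) & usable
    c = (concordant.sum() + 0.5 * tied_score.sum()) / n_usable
    return float(c), n_usable


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank, stratification, calibration
# ---------------------------------------------------------------------------


def km_logrank(time, event, groups) -> dict:
    """Per-group Kaplan-Meier curves and the 2-sample log-rank test.

    Returns a dict with ``curves`` (group -> DataFrame[time, survival]),
    ``chi2`` and ``p`` (1 df).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups, got {len(labels)}")
    curves = {}
    for g in labels:
        m = groups == g
        if m.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        km = KaplanMeierFitter()
        km.fit(time[m], event[m])
        curves[g] = pd.DataFrame(
            {"time": km.survival_function_.index.to_numpy(),
             "survival": km.survival_function_.iloc[:, 0].to_numpy()}
        )
    m0 = groups == labels[0]
    res = logrank_test(time[m0], time[~m0], event[m0], event[~m0])
    return {"curves": curves, "chi2": float(res.test_statistic), "p": float(res.p_value),
            "labels": list(labels)}


def stratify_by_median(training_scores, scores=None) -> dict:
    """Median-threshold risk stratification.

    The threshold is the median of the *training* scores; a patient is
    high-risk iff score >= threshold (scores equal to the median go to the
    high-risk group).
    """
    training_scores = np.asarray(training_scores, dtype=float)
    if training_scores.size == 0:
        raise ValueError("training scores are empty")
    threshold = float(np.median(training_scores))
    if scores is None:
        scores = training_scores
    scores = np.asarray(scores, dtype=float)
    group = np.where(scores >= threshold, "high", "low")
    return {"threshold": threshold, "group": group}


def _km_at(time, event, horizon) -> float:
    km = KaplanMeierFitter()
    km.fit(time, event)
    return float(km.predict(horizon))


def calibration_curve(
    results: CoxPHResults,
    X: pd.DataFrame,
    time,
    event,
    horizon: float,
    n_groups: int = 4,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Predicted vs observed event-free probability at a fixed horizon.

    Patients are grouped into ``n_groups`` quantiles of predicted
    S(horizon); per group, observed = Kaplan-Meier estimate at the horizon
    with a bootstrap percentile CI.  If the horizon exceeds the last
    follow-up time a warning is raised and the horizon is truncated.
    """
    import warnings

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if horizon > time.max():
        warnings.warn(
            f"horizon {horizon} beyond last follow-up {time.max():.1f}; truncating",
            stacklevel=2,
        )
        horizon = float(time.max())
    pred = results.predict_survival(X, [horizon])[:, 0]
    if horizon == 0:
        order_groups = np.zeros(len(pred), dtype=int)
        n_groups = 1
    else:
        qs = np.quantile(pred, np.linspace(0, 1, n_groups + 1)[1:-1])
        order_groups = np.searchsorted(qs, pred, side="right")
    rng = rng or np.random.default_rng(0)
    rows = []
    for g in range(n_groups):
        m = order_groups == g
        if m.sum() == 0:
            continue
        obs = _km_at(time[m], event[m], horizon)
        boots = []
        idx = np.flatnonzero(m)
        for _ in range(n_boot):
            bs = rng.choice(idx, size=len(idx), replace=True)
            try:
                boots.append(_km_at(time[bs], event[bs], horizon))
            except Exception:
                continue
        lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
        rows.append(
            {"group": g, "n": int(m.sum()), "predicted": float(pred[m].mean()),
             "observed": obs, "observed_lo": float(lo), "observed_hi": float(hi)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort split and baseline characteristics
# ---------------------------------------------------------------------------


def split_cohort(n_or_ids, seed: int = 0, ratio: tuple[int, int] = (4, 3)):
    """Seeded random 4:3 split into training and validation index arrays.

    Training size = round(n * 4 / 7); 140 patients give 80/60.  The split is
    a seeded permutation: disjoint, exhaustive, reproducible.
    """
    if np.isscalar(n_or_ids):
        ids = np.arange(int(n_or_ids))
    else:
        ids = np.asarray(n_or_ids)
    n = len(ids)
    if n < sum(ratio):
        raise ValueError(f"need at least {sum(ratio)} patients for a {ratio[0]}:{ratio[1]} split")
    n_train = int(round(n * ratio[0] / sum(ratio)))
    perm = np.random.default_rng(seed).permutation(n)
    return ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]


def baseline_table(train_clinical: pd.DataFrame, valid_clinical: pd.DataFrame) -> pd.DataFrame:
    """Training-vs-validation comparison of baseline characteristics.

    Mann-Whitney U for age (continuous); chi-square for gender, T stage,
    N stage, histology, and hemoglobin / platelets dichotomized at the
    study cutoffs (136 g/L, 238 x 10^9/L).  Two-sided p-values.
    """
    import warnings

    rows = []

    def _chi2(a: pd.Series, b: pd.Series, name: str):
        cats = sorted(set(a.unique()) | set(b.unique()))
        table = np.array(
            [[int((a == c).sum()) for c in cats], [int((b == c).sum()) for c in cats]]
        )
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            rows.append({"variable": name, "test": "chi2", "statistic": 0.0, "p": 1.0})
            return
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        if (expected < 5).any():
            warnings.warn(f"low expected counts in chi-square for {name}", stacklevel=3)
        rows.append({"variable": name, "test": "chi2", "statistic": float(chi2), "p": float(p)})

    u = stats.mannwhitneyu(train_clinical["age"], valid_clinical["age"], alternative="two-sided")
    rows.append({"variable": "age", "test": "mannwhitneyu",
                 "statistic": float(u.statistic), "p": float(u.pvalue)})
    _chi2(train_clinical["gender"], valid_clinical["gender"], "gender")
    _chi2(train_clinical["t_stage"], valid_clinical["t_stage"], "t_stage")
    _chi2(train_clinical["n_stage"], valid_clinical["n_stage"], "n_stage")
    _chi2(train_clinical["histology"], valid_clinical["histology"], "histology")
    _chi2(train_clinical["hgb"] >= 136, valid_clinical["hgb"] >= 136, "hgb>=136")
    _chi2(train_clinical["platelets"] >= 238, valid_clinical["platelets"] >= 238, "platelets>=238")
    return pd.DataFrame(rows).set_index("variable")


def backward_eliminate(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    p_threshold: float = 0.05,
) -> CoxPHResults:
    """Backward elimination on Wald p-values, keeping at least one covariate.

    Repeatedly drops the least significant covariate with p >= threshold
    and refits; used for the clinical-only comparison model.
    """
    current = list(covariates)
    while True:
        res = CoxPH(data, duration_col, event_col, current).fit()
        if len(current) == 1:
            return res
        p = res.p_values_
        worst = p.idxmax()
        if p[worst] < p_threshold:
            return res
        current.remove(worst)
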