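"""Points-based nomogram over a fitted combined Cox model, and renderers.

Each predictor's contribution beta_i * x_i is mapped linearly to a
nonnegative point scale anchored at the value minimizing the contribution
over the predictor's observed range (its minimum for beta > 0, its maximum
for beta < 0); the predictor with the largest contribution span covers
exactly 0-100 points.  Total points are an affine transform of the linear
predictor, so the lookup total points -> 2/3-year recurrence-free
probability through the model's Breslow baseline hazard reproduces the Cox
model's S(t | x) exactly under continuous point arithmetic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from radnomics.survival import CoxPHResults

__all__ = ["NomogramSpec", "build_nomogram", "render_nomogram", "render_calibration", "render_km"]


@dataclass
class NomogramSpec:
    """Per-predictor point scales and the total-points -> S(t) lookup."""

    predictors: list[str]
    coefficients: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    scale: float  # points per unit of linear predictor
    lp_offset: float  # linear predictor at zero total points
    lp_center: float  # beta' xbar of the training data (baseline anchoring)
    horizons: tuple[float, ...]
    baseline_cumhaz: dict[float, float]  # horizon -> Lambda0(horizon)

    def points(self, name: str, value) -> np.ndarray:
        """Points awarded to predictor ``name`` at ``value`` (linear, >= 0)."""
        beta = self.coefficients[name]
        lo, hi = self.ranges[name]
        anchor = lo if beta >= 0 else hi
        return np.abs(beta) * (np.asarray(value, dtype=float) - anchor) * np.sign(beta) * self.scale

    def total_points(self, X: pd.DataFrame) -> np.ndarray:
        return sum(self.points(name, X[name].to_numpy()) for name in self.predictors)

    def survival_from_points(self, total_points, horizon: float) -> np.ndarray:
        """Map total points to S(horizon) through the Cox baseline hazard."""
        lp = np.asarray(total_points, dtype=float) / self.scale + self.lp_offset
        lam0 = self.baseline_cumhaz[float(horizon)]
        return np.exp(-lam0 * np.exp(lp - self.lp_center))

    def to_json(self, path) -> None:
        payload = {
            "predictors": self.predictors,
            "coefficients": self.coefficients,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "scale": self.scale,
            "lp_offset": self.lp_offset,
            "lp_center": self.lp_center,
            "horizons": list(self.horizons),
            "baseline_cumhaz": {str(k): v for k, v in self.baseline_cumhaz.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_nomogram(
    results: CoxPHResults,
    covariate_ranges: dict[str, tuple[float, float]],
    horizons=(24.0, 36.0),
) -> NomogramSpec:
    """Build the nomogram spec from a fitted Cox model and covariate ranges.

    Predictors with a zero coefficient carry no points and are dropped with
    a warning.  The largest contribution span maps to 100 points.
    """
    predictors, coefs, ranges = [], {}, {}
    for name, beta in results.params_.items():
        lo, hi = (float(covariate_ranges[name][0]), float(covariate_ranges[name][1]))
        if not np.isfinite([lo, hi]).all():
            raise ValueError(f"non-finite range for {name}")
        if beta == 0 or lo == hi:
            warnings.warn(f"predictor {name!r} carries no points; dropped", stacklevel=2)
            continue
        predictors.append(name)
        coefs[name] = float(beta)
        ranges[name] = (lo, hi)
    if not predictors:
        raise ValueError("no predictor with a nonzero point span")
    max_span = max(abs(coefs[n]) * (ranges[n][1] - ranges[n][0]) for n in predictors)
    scale = 100.0 / max_span
    lp_offset = sum(
        coefs[n] * (ranges[n][0] if coefs[n] >= 0 else ranges[n][1]) for n in predictors
    )
    # account for any dropped zero-coefficient predictors in the centering
    lp_center = float(results.covariate_means_ @ results.params_)
    lam0 = {float(h): float(results.baseline_cumulative_hazard(h)[0]) for h in horizons}
    return NomogramSpec(
        predictors=predictors,
        coefficients=coefs,
        ranges=ranges,
        scale=scale,
        lp_offset=lp_offset,
        lp_center=lp_center,
        horizons=tuple(float(h) for h in horizons),
        baseline_cumhaz=lam0,
    )


# ---------------------------------------------------------------------------
# Renderers (vector graphics)
# ---------------------------------------------------------------------------


def _scale_axis(ax, title: str, lo: float, hi: float, point_lo: float, point_hi: float):
    ax.set_xlim(-2, 102)
    ax.set_yticks([])
    ax.spines[["left", "right", "top"]].set_visible(False)
    ax.set_ylabel(title, rotation=0, ha="right", va="center", fontsize=9)
    ticks = np.linspace(lo, hi, 6)
    pts = np.linspace(point_lo, point_hi, 6)
    ax.set_xticks(pts)
    ax.set_xticklabels([f"{t:g}" for t in np.round(ticks, 2)], fontsize=7)


def render_nomogram(spec: NomogramSpec, outpath) -> int:
    """Render the nomogram as one horizontal scale per axis (SVG/PDF).

    Axes: a 0-100 points ruler, one scale per predictor, a total-points
    ruler, and one probability scale per horizon.  Returns the axis count
    (a 6-predictor model with 2 horizons renders 10 axes).
    """
    n_axes = 1 + len(spec.predictors) + 1 + len(spec.horizons)
    fig, axes = plt.subplots(n_axes, 1, figsize=(8, 0.7 * n_axes + 1))
    axes = np.atleast_1d(axes)

    ax = axes[0]
    ax.set_xlim(-2, 102)
    ax.set_yticks([])
    ax.spines[["left", "right", "top"]].set_visible(False)
    ax.set_ylabel("Points", rotation=0, ha="right", va="center", fontsize=9)
    ax.set_xticks(np.linspace(0, 100, 11))

    for k, name in enumerate(spec.predictors):
        lo, hi = spec.ranges[name]
        p_lo = float(spec.points(name, lo))
        p_hi = float(spec.points(name, hi))
        _scale_axis(axes[1 + k], name, lo, hi, p_lo, p_hi)

    total_max = sum(
        max(float(spec.points(n, spec.ranges[n][0])), float(spec.points(n, spec.ranges[n][1])))
        for n in spec.predictors
    )
    ax = axes[1 + len(spec.predictors)]
    ax.set_xlim(-2, 102)
    ax.set_yticks([])
    ax.spines[["left", "right", "top"]].set_visible(False)
    ax.set_ylabel("Total points", rotation=0, ha="right", va="center", fontsize=9)
    tp_ticks = np.linspace(0, total_max, 6)
    ax.set_xticks(np.linspace(0, 100, 6))
    ax.set_xticklabels([f"{t:.0f}" for t in tp_ticks], fontsize=7)

    for j, h in enumerate(spec.horizons):
        ax = axes[2 + len(spec.predictors) + j]
        ax.set_xlim(-2, 102)
        ax.set_yticks([])
        ax.spines[["left", "right", "top"]].set_visible(False)
        ax.set_ylabel(f"S({h:g} mo)", rotation=0, ha="right", va="center", fontsize=9)
        tp = np.linspace(0, total_max, 6)
        probs = spec.survival_from_points(tp, h)
        ax.set_xticks(np.linspace(0, 100, 6))
        ax.set_xticklabels([f"{p:.2f}" for p in probs], fontsize=7)

    fig.tight_layout()
    fig.savefig(outpath)
    plt.close(fig)
    return n_axes


def render_calibration(curves: dict[float, pd.DataFrame], outpath) -> None:
    """Plot predicted vs observed event-free probability per horizon."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k:", lw=1, label="ideal")
    for h, tab in curves.items():
        err = np.abs(tab[["observed_lo", "observed_hi"]].to_numpy().T - tab["observed"].to_numpy())
        ax.errorbar(tab["predicted"], tab["observed"], yerr=err, marker="o",
                    capsize=3, label=f"{h:g} months")
    ax.set_xlabel("Predicted recurrence-free probability")
    ax.set_ylabel("Observed (Kaplan-Meier)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(outpath)
    plt.close(fig)


def render_km(time, event, groups, outpath) -> None:
    """Kaplan-Meier curves per risk group with censor marks and at-risk counts."""
    from lifelines import KaplanMeierFitter
    from lifelines.plotting import add_at_risk_counts

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(6, 5))
    fitters = []
    for g in pd.unique(groups):
        m = groups == g
        km = KaplanMeierFitter(label=str(g))
        km.fit(time[m], event[m])
        km.plot_survival_function(ax=ax, show_censors=True)
        fitters.append(km)
    add_at_risk_counts(*fitters, ax=ax)
    ax.set_xlabel("Months")
    ax.set_ylabel("Local-recurrence-free survival")
    fig.tight_layout()
    fig.savefig(outpath)
    plt.close(fig)
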