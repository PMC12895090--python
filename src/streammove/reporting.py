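"""Posterior summaries: coefficient tables, posterior probabilities of
effect signs, and predicted movement bands.

A coefficient's *posterior probability* is the larger of the posterior
mass above and below zero; 0.95 or more is flagged as a robust effect.
Movement bands are the central 50% and 90% ranges of predicted absolute
displacement |X1 - X0| along a covariate grid, pooling the posterior:
under the t kernel the predicted displacement is a mixture over draws of
folded-t distributions with scale sigma_d = exp(beta0_d + beta_d.x + ln
eta_ref), and the band endpoint at level q solves the mixture CDF
mean_d[2 T_nu(q/sigma_d) - 1] = q numerically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import stdtr
from scipy.stats import t as t_dist

from .mcmc import ConvergenceReport, PosteriorDraws

ROBUSTNESS_THRESHOLD = 0.95


def posterior_probability(samples) -> float:
    """max(P(theta > 0), P(theta < 0)) from MCMC samples; exact zeros are
    split evenly between the two sides."""
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("posterior_probability of an empty sample")
    half_zero = 0.5 * np.mean(s == 0.0)
    p_pos = np.mean(s > 0.0) + half_zero
    p_neg = np.mean(s < 0.0) + half_zero
    return float(max(p_pos, p_neg))


@dataclass
class CoefficientSummary:
    parameter: str
    median: float
    ci_lower: float
    ci_upper: float
    posterior_probability: float
    robust: bool


def summarize_coefficients(
    draws: PosteriorDraws, parameters: tuple[str, ...] | None = None
) -> list[CoefficientSummary]:
    """Median, equal-tailed 95% credible interval, posterior probability
    and robustness flag for each parameter, pooled across chains."""
    parameters = parameters or draws.param_names
    out = []
    for name in parameters:
        s = draws.pooled(name)
        lo, med, hi = np.percentile(s, [2.5, 50.0, 97.5])
        pp = posterior_probability(s)
        out.append(
            CoefficientSummary(
                parameter=name,
                median=float(med),
                ci_lower=float(lo),
                ci_upper=float(hi),
                posterior_probability=pp,
                robust=pp >= ROBUSTNESS_THRESHOLD,
            )
        )
    return out


def coefficient_table(
    summaries: list[CoefficientSummary],
) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


@dataclass
class MovementBand:
    """Predicted movement ranges along a covariate grid at a reference
    interval ``eta_ref``: for each grid point, ``bounds[level]`` is the
    distance within which that fraction of individuals is predicted to
    remain (absolute displacement), or the central signed range."""

    grid: pd.DataFrame
    eta_ref: float
    levels: tuple[float, ...]
    bounds: dict[float, np.ndarray] = field(default_factory=dict)
    absolute: bool = True


def _mixture_abs_quantile(sigmas: np.ndarray, nu: float, level: float) -> float:
    """Quantile of |X| where X is an equal-weight mixture of centred
    t_nu distributions with the given scales."""

    def cdf(q):
        return float(np.mean(2.0 * stdtr(nu, q / sigmas) - 1.0)) - level

    hi = float(np.max(sigmas)) * t_dist.ppf(0.5 + level / 2.0, nu) * 4.0 + 1.0
    while cdf(hi) < 0:
        hi *= 2.0
    return brentq(cdf, 0.0, hi, xtol=1e-10)


def movement_band(
    draws: PosteriorDraws,
    grid: pd.DataFrame,
    eta_ref: float = 93.0,
    levels: tuple[float, ...] = (0.5, 0.9),
    nu: float = 5.0,
) -> MovementBand:
    """Predicted 50%/90% absolute-movement bands along a covariate grid.

    ``grid`` columns name covariates on the standardized scale used in
    fitting; covariates absent from the grid are held at 0 (their mean).
    Unknown columns raise.
    """
    beta_cols = [n for n in draws.param_names if n.startswith("beta_")]
    cov_names = [n[len("beta_"):] for n in beta_cols]
    unknown = set(grid.columns) - set(cov_names)
    if unknown:
        raise KeyError(
            f"grid columns {sorted(unknown)} unknown to the fitted model "
            f"(covariates: {cov_names})"
        )
    beta0 = draws.pooled("beta0")
    B = np.column_stack([draws.pooled(c) for c in beta_cols])  # (d, k)
    Xg = np.zeros((len(grid), len(cov_names)))
    for j, name in enumerate(cov_names):
        if name in grid.columns:
            Xg[:, j] = grid[name].to_numpy(dtype=float)

    bounds = {lv: np.empty(len(grid)) for lv in levels}
    for g in range(len(grid)):
        sigmas = np.exp(beta0 + B @ Xg[g] + np.log(eta_ref))
        for lv in levels:
            bounds[lv][g] = _mixture_abs_quantile(sigmas, nu, lv)
    return MovementBand(
        grid=grid.copy(), eta_ref=eta_ref, levels=tuple(levels), bounds=bounds
    )


def species_report(
    summaries: list[CoefficientSummary],
    bands: list[MovementBand] | None = None,
    diagnostics: ConvergenceReport | None = None,
    species: str | None = None,
) -> dict:
    """Machine-readable report for one species' fit."""
    report: dict = {"species": species, "coefficients": [asdict(s) for s in summaries]}
    if diagnostics is not None:
        report["convergence"] = {
            "max_rhat": diagnostics.max_rhat,
            "threshold": diagnostics.threshold,
            "passed": diagnostics.passed,
            "rhat": {
                row.parameter: row.rhat
                for row in diagnostics.table.itertuples()
            },
        }
        report["converged"] = diagnostics.passed
    if bands:
        report["bands"] = [
            {
                "eta_ref": b.eta_ref,
                "levels": list(b.levels),
                "grid": b.grid.to_dict(orient="list"),
                "bounds": {str(lv): v.tolist() for lv, v in b.bounds.items()},
            }
            for b in bands
        ]
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)


def report_text(report: dict) -> str:
    """Human-readable coefficient table, flagging non-convergence."""
    lines = []
    if report.get("species"):
        lines.append(f"Species: {report['species']}")
    conv = report.get("convergence")
    if conv is not None and not conv["passed"]:
        lines.append(
            f"*** WARNING: chains did NOT converge "
            f"(max R-hat {conv['max_rhat']:.3f} >= {conv['threshold']}) ***"
        )
    lines.append(
        f"{'parameter':<26s}{'median':>10s}{'2.5%':>10s}{'97.5%':>10s}"
        f"{'Pr(sign)':>10s}  robust"
    )
    for c in report["coefficients"]:
        lines.append(
            f"{c['parameter']:<26s}{c['median']:>10.3f}{c['ci_lower']:>10.3f}"
            f"{c['ci_upper']:>10.3f}{c['posterior_probability']:>10.3f}"
            f"  {'*' if c['robust'] else ''}"
        )
    return "\n".join(lines)


def plot_band(band: MovementBand, column: str, ax=None):
    """Convenience plot of a movement band along one grid column."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = band.grid[column].to_numpy(dtype=float)
    shades = {0.9: 0.2, 0.5: 0.4}
    for lv in sorted(band.levels, reverse=True):
        ax.fill_between(
            x, 0.0, band.bounds[lv],
            alpha=shades.get(lv, 0.3), label=f"{int(lv * 100)}%",
        )
    ax.set_xlabel(f"{column} (standardized)")
    ax.set_ylabel(f"absolute movement (m / {band.eta_ref:.0f} d)")
    ax.legend()
    return ax
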