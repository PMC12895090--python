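"""Model/Results front-end for the dispersal-observation model.

:class:`DispersalObservationModel` is built from movement-replicate data
(a list of replicates with covariates attached, a :class:`ReplicateData`,
or a plain DataFrame); ``fit()`` runs the MCMC and returns a
:class:`DispersalResults` carrying the posterior draws, convergence
diagnostics, coefficient summaries and predicted movement bands.

    >>> model = DispersalObservationModel.from_dataframe(df, ["body_size"])
    >>> res = model.fit(SamplerConfig(n_iter=4000, burn_in=1500, thin=5))
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import CovariateMatrix
from .likelihood import (
    ModelConfig,
    ModelParams,
    ReplicateData,
    log_prior,
    marginal_loglik,
)
from .mcmc import (
    ConvergenceReport,
    PosteriorDraws,
    SamplerConfig,
    check_convergence,
    sample_posterior,
)
from .reporting import (
    CoefficientSummary,
    MovementBand,
    coefficient_table,
    movement_band,
    posterior_probability,
    report_text,
    species_report,
    summarize_coefficients,
    write_report,
)


class DispersalObservationModel:
    """Heavy-tailed movement kernel with covariate-dependent dispersion,
    coupled to a Bernoulli recapture process with permanent emigration."""

    def __init__(
        self,
        data: ReplicateData,
        config: ModelConfig | None = None,
        covariates: CovariateMatrix | None = None,
        species: str | None = None,
    ):
        if not isinstance(data, ReplicateData):
            raise TypeError(
                "data must be a ReplicateData; use from_replicates / "
                "from_dataframe to construct one"
            )
        self.data = data
        self.config = config or ModelConfig()
        self.covariates = covariates
        self.species = species

    @classmethod
    def from_replicates(
        cls,
        replicates,
        config: ModelConfig | None = None,
        covariates: CovariateMatrix | None = None,
        species: str | None = None,
    ) -> "DispersalObservationModel":
        """Build from a list of :class:`~streammove.io.MovementReplicate`
        with covariates already attached (see ``assemble_covariates``)."""
        if not replicates:
            raise ValueError("no replicates supplied")
        beta_names = (
            covariates.columns if covariates is not None else None
        )
        data = ReplicateData.from_replicates(replicates, beta_names=beta_names)
        return cls(data, config=config, covariates=covariates, species=species)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariate_cols: list[str],
        config: ModelConfig | None = None,
        species: str | None = None,
    ) -> "DispersalObservationModel":
        """Build from a DataFrame with columns ``x0, x1, y, eta_days`` plus
        the (already standardized) covariate columns; ``x1`` may be NaN
        where ``y == 0``."""
        required = {"x0", "x1", "y", "eta_days"}
        missing = required - set(df.columns)
        if missing:
            raise KeyError(f"dataframe missing columns {sorted(missing)}")
        data = ReplicateData(
            x0=df["x0"].to_numpy(dtype=float),
            x1=df["x1"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=bool),
            eta=df["eta_days"].to_numpy(dtype=float),
            X=df[covariate_cols].to_numpy(dtype=float),
            beta_names=tuple(covariate_cols),
            replicate_ids=tuple(str(i) for i in df.index),
        )
        return cls(data, config=config, species=species)

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("beta0", *(f"beta_{n}" for n in self.data.beta_names), "phi")

    def loglike(self, params: ModelParams) -> float:
        """Marginalized log-likelihood at the given parameters."""
        return marginal_loglik(
            self.data, params.beta0, params.beta, params.phi, self.config
        )

    def logpost(self, params: ModelParams) -> float:
        return self.loglike(params) + log_prior(params, self.config)

    def fit(
        self,
        sampler_config: SamplerConfig | None = None,
        mode: str = "marginalized",
    ) -> "DispersalResults":
        draws = sample_posterior(
            self.data, self.config, sampler_config, mode=mode
        )
        return DispersalResults(self, draws)


class DispersalResults:
    """Posterior draws and derived summaries from a fitted model."""

    def __init__(self, model: DispersalObservationModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._convergence: ConvergenceReport | None = None

    @property
    def params(self) -> pd.Series:
        """Posterior medians."""
        return pd.Series(
            {
                n: float(np.median(self.draws.pooled(n)))
                for n in self.draws.param_names
            },
            name="median",
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Equal-tailed (1 - alpha) credible intervals."""
        rows = {}
        for n in self.draws.param_names:
            s = self.draws.pooled(n)
            rows[n] = np.percentile(s, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["lower", "upper"]
        )

    @property
    def posterior_probabilities(self) -> pd.Series:
        return pd.Series(
            {
                n: posterior_probability(self.draws.pooled(n))
                for n in self.draws.param_names
            },
            name="posterior_probability",
        )

    @property
    def convergence(self) -> ConvergenceReport:
        if self._convergence is None:
            self._convergence = check_convergence(self.draws)
        return self._convergence

    @property
    def max_rhat(self) -> float:
        return self.convergence.max_rhat

    def coefficient_summaries(self) -> list[CoefficientSummary]:
        return summarize_coefficients(self.draws)

    def movement_band(
        self,
        grid: pd.DataFrame,
        eta_ref: float = 93.0,
        levels: tuple[float, ...] = (0.5, 0.9),
    ) -> MovementBand:
        return movement_band(
            self.draws, grid, eta_ref=eta_ref, levels=levels,
            nu=self.model.config.nu,
        )

    def report(self, bands: list[MovementBand] | None = None) -> dict:
        return species_report(
            self.coefficient_summaries(),
            bands=bands,
            diagnostics=self.convergence,
            species=self.model.species,
        )

    def summary(self) -> str:
        """Text summary: coefficient table plus convergence verdict."""
        header = [
            "Dispersal-observation model"
            + (f" — {self.model.species}" if self.model.species else ""),
            f"replicates: {self.model.data.n} "
            f"(recaptured: {int(self.model.data.y.sum())}), "
            f"nu={self.model.config.nu:g}, L={self.model.config.L:g} m",
            f"chains: {self.draws.n_chains}, kept draws/chain: "
            f"{self.draws.n_kept}, mode: {self.draws.metadata.get('mode')}",
            "",
        ]
        return "\n".join(header) + report_text(self.report())

    def save(self, outdir, prefix: str = "fit") -> None:
        """Serialize draws (CSV + JSON sidecar), coefficient table and
        report into ``outdir``."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.draws.save(
            outdir / f"{prefix}_draws.csv", outdir / f"{prefix}_draws_meta.json"
        )
        coefficient_table(self.coefficient_summaries()).to_csv(
            outdir / f"{prefix}_coefficients.csv", index=False
        )
        write_report(self.report(), outdir / f"{prefix}_report.json")
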