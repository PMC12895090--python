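"""Density surfaces and the standardized predictor matrix.

Fish density enters the dispersion model as a *distance-weighted* density:
the detection-corrected density of every section, down-weighted by
``exp(-lambda * distance)`` from the focal section's midpoint, so that
neighbours within roughly ``1/lambda`` metres dominate while farther fish
still contribute.  Predictors are standardized the way the movement model
expects: z-scores for body size, the four species densities and Julian day;
per-occasion ratio normalization (divide by the cross-sectional occasion
mean) for habitat refuge area and current velocity, which removes seasonal
level shifts while preserving spatial contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CaptureRecord, MovementReplicate, Occasion, section_midpoint

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.1  # 1/m; density influence strongest within ~10 m

ZSCORE_COLUMNS_BASE = ("body_size", "julian_day")
RATIO_COLUMNS = ("hra", "velocity")


@dataclass
class DensitySurface:
    """Per-species density over occasion x section.

    ``corrected`` is count / (p_detect * area) in fish per m^2;
    ``weighted`` is the exponential-kernel smoothing of ``corrected``
    along the reach.
    Both are DataFrames indexed by occasion with one column per section.
    """

    species: str
    counts: pd.DataFrame
    corrected: pd.DataFrame
    weighted: pd.DataFrame
    lambda_: float

    def weighted_at(self, occasion: int, section: int) -> float:
        try:
            return float(self.weighted.at[occasion, section])
        except KeyError:
            raise KeyError(
                f"density surface for {self.species}: no cell "
                f"(occasion={occasion}, section={section})"
            ) from None


@dataclass
class CovariateMatrix:
    """Replicate-aligned predictors plus the standardization metadata
    needed to put new (prediction-grid) values on the fitted scale."""

    data: pd.DataFrame
    zscore_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    occasion_means: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def standardize_new(self, column: str, values) -> np.ndarray:
        """Map raw values of a z-scored column onto the fitted scale."""
        if column not in self.zscore_stats:
            raise KeyError(f"{column!r} is not a z-scored covariate")
        mean, sd = self.zscore_stats[column]
        return (np.asarray(values, dtype=float) - mean) / sd


def corrected_density(count: int, area_m2: float, p_detect: float) -> float:
    """Detection-corrected density (individuals per m^2): count / (p * area)."""
    if p_detect <= 0 or p_detect > 1:
        raise ValueError(f"p_detect must be in (0, 1], got {p_detect}")
    if area_m2 <= 0:
        raise ValueError(f"area must be positive, got {area_m2}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count / (p_detect * area_m2)


def distance_weighted_density(
    D, midpoints, lambda_: float = DEFAULT_LAMBDA
) -> np.ndarray:
    """Exponentially distance-weighted density over sections.

    ``out[s] = sum_s' D[s'] * exp(-lambda * |m_s - m_s'|)`` — including the
    focal section itself with weight 1.
    """
    D = np.asarray(D, dtype=float)
    m = np.asarray(midpoints, dtype=float)
    if D.shape != m.shape:
        raise ValueError("D and midpoints must have the same length")
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    if (D < 0).any():
        raise ValueError("densities must be non-negative")
    W = np.exp(-lambda_ * np.abs(m[:, None] - m[None, :]))
    return W @ D


def zscore(values) -> tuple[np.ndarray, float, float]:
    """Standardize to mean 0, sample (n-1) standard deviation 1.

    Returns ``(standardized, mean, sd)``; raises on constant input, whose
    scale is undefined.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("zscore needs at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zscore undefined for a constant vector")
    return (v - mean) / sd, mean, sd


def ratio_normalize(values, occasion_ids) -> np.ndarray:
    """Divide each value by its occasion's cross-sectional mean.

    An occasion whose values are all zero is left at zero (with a logged
    warning) rather than raising, since a structure-free occasion carries
    no spatial contrast to preserve.
    """
    v = np.asarray(values, dtype=float)
    occ = np.asarray(occasion_ids)
    if v.shape != occ.shape:
        raise ValueError("values and occasion_ids must have the same length")
    out = np.empty_like(v)
    for o in np.unique(occ):
        mask = occ == o
        mean = v[mask].mean()
        if mean == 0.0:
            logger.warning(
                "ratio_normalize: occasion %s has zero cross-sectional mean; "
                "outputs set to 0",
                o,
            )
            out[mask] = 0.0
        else:
            out[mask] = v[mask] / mean
    return out


def build_density_surface(
    records: list[CaptureRecord],
    habitat: pd.DataFrame,
    species: str,
    p_detect: pd.DataFrame | float = 1.0,
    lambda_: float = DEFAULT_LAMBDA,
    section_length: float = 10.0,
    source: str = "all",
    tagging_threshold_mm: float = 60.0,
) -> DensitySurface:
    """Count captures of one species per occasion x section and convert to
    detection-corrected, distance-weighted densities.

    ``p_detect`` is either a scalar or a table with columns
    (species, occasion, p_detect); the default 1.0 yields raw densities and
    logs a warning, since uncorrected counts understate true density.
    ``source='tagged'`` restricts counts to individuals above the tagging
    threshold.
    """
    occasions = sorted(habitat["occasion"].unique())
    sections = sorted(habitat["section"].unique())
    counts = pd.DataFrame(0, index=occasions, columns=sections, dtype=float)
    for rec in records:
        if rec.species != species:
            continue
        if source == "tagged" and rec.total_length_mm <= tagging_threshold_mm:
            continue
        counts.at[rec.occasion, rec.section] += 1

    area = habitat.pivot(index="occasion", columns="section", values="area_m2")
    area = area.reindex(index=occasions, columns=sections)
    if area.isna().any().any():
        raise KeyError(f"habitat table missing area cells for {species}")

    if np.isscalar(p_detect):
        if p_detect == 1.0:
            logger.warning(
                "build_density_surface(%s): no detection probabilities "
                "supplied; using raw (uncorrected) densities",
                species,
            )
        p = pd.Series(float(p_detect), index=occasions)
    else:
        sub = p_detect[p_detect["species"] == species].set_index("occasion")
        p = sub["p_detect"].reindex(occasions)
        if p.isna().any():
            raise KeyError(
                f"detection table missing occasions for {species}: "
                f"{sorted(p.index[p.isna()])}"
            )
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("detection probabilities must be in (0, 1]")

    corrected = counts.div(area).div(p, axis=0)
    midpoints = np.array(
        [section_midpoint(s, section_length) for s in sections]
    )
    weighted = corrected.copy()
    for occ in occasions:
        weighted.loc[occ] = distance_weighted_density(
            corrected.loc[occ].to_numpy(), midpoints, lambda_
        )
    return DensitySurface(
        species=species,
        counts=counts,
        corrected=corrected,
        weighted=weighted,
        lambda_=lambda_,
    )


def assemble_covariates(
    replicates: list[MovementReplicate],
    surfaces: dict[str, DensitySurface],
    habitat: pd.DataFrame,
    occasions: list[Occasion],
) -> CovariateMatrix:
    """Build the standardized predictor matrix for one species' model fit.

    Looks up every replicate's covariates at its capture occasion and
    section, z-scores body size, each species' weighted density and Julian
    day over the replicate rows entering this fit, and ratio-normalizes HRA
    and velocity by occasion.  The resulting column values are written back
    onto each replicate's ``covariates`` dict.
    """
    if not replicates:
        raise ValueError("no replicates to assemble covariates for")
    occ_by_index = {o.index: o for o in occasions}

    hab = habitat.copy()
    hab["hra"] = ratio_normalize(
        hab["hra_m2"].to_numpy(), hab["occasion"].to_numpy()
    )
    hab["velocity"] = ratio_normalize(
        hab["velocity_ms"].to_numpy(), hab["occasion"].to_numpy()
    )
    hab = hab.set_index(["occasion", "section"])

    raw: dict[str, list[float]] = {"body_size": [], "julian_day": []}
    species_cols = [f"density_{sp}" for sp in surfaces]
    for col in species_cols:
        raw[col] = []
    raw["hra"], raw["velocity"] = [], []

    for rep in replicates:
        if rep.total_length_mm is None or rep.section_t is None:
            raise ValueError(
                f"replicate {rep.replicate_id} lacks capture length/section"
            )
        raw["body_size"].append(rep.total_length_mm)
        raw["julian_day"].append(float(occ_by_index[rep.occasion_t].julian_day))
        for sp, surf in surfaces.items():
            raw[f"density_{sp}"].append(
                surf.weighted_at(rep.occasion_t, rep.section_t)
            )
        key = (rep.occasion_t, rep.section_t)
        if key not in hab.index:
            raise KeyError(
                f"habitat table missing cell (occasion={key[0]}, "
                f"section={key[1]})"
            )
        raw["hra"].append(float(hab.at[key, "hra"]))
        raw["velocity"].append(float(hab.at[key, "velocity"]))

    data = {}
    zstats = {}
    for col in ("body_size", *species_cols, "julian_day"):
        z, mean, sd = zscore(raw[col])
        data[col] = z
        zstats[col] = (mean, sd)
    for col in RATIO_COLUMNS:
        data[col] = np.asarray(raw[col], dtype=float)

    df = pd.DataFrame(data, index=[r.replicate_id for r in replicates])
    occ_means = {
        col: habitat.groupby("occasion")[src].mean().to_dict()
        for col, src in (("hra", "hra_m2"), ("velocity", "velocity_ms"))
    }
    cm = CovariateMatrix(data=df, zscore_stats=zstats, occasion_means=occ_means)
    for rep, (_, row) in zip(replicates, df.iterrows()):
        rep.covariates = {c: float(row[c]) for c in df.columns}
    return cm
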