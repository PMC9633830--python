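"""Synthetic cohort generator.

Emulates a rural child biomonitoring survey: ~400 children in a handful of
clustered village areas inside a ~0.1 degree box, each with serum
concentrations of four trace metals (As, Cd, Hg, Pb) plus micronutrient
and growth covariates. Latent concentrations are lognormal with spatially
autocorrelated log-fields (exponential covariance), selected
analyte/covariate pairs share a latent field through a linear model of
coregionalization (Z_cov = rho * Z_metal + sqrt(1 - rho^2) * Z_indep), and
observations are left-censored at the configured LoD/LoQ. The truth table
is retained alongside the censored observations so parameter recovery is
measurable end to end.

Default marginals are derived in closed form from published target
quantities: per-metal censoring fractions fix (mu, sigma) of each
lognormal via the Gaussian quantiles of P(X < LoD) and P(X < LoQ), and
each covariate's spread comes from its deficiency-prevalence target and
median. All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawns; the streams are, in order: sites,
one per analyte field, one per covariate field.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import cholesky
from scipy.stats import norm

from .censoring import PUBLISHED_LIMITS, CensoredSeries, DetectionLimits, classify
from .errors import ConfigurationError, NumericalError
from .geo import EARTH_RADIUS_M, pairwise_haversine

#: Default study window, decimal degrees (lon_min, lat_min, lon_max, lat_max):
#: a ~0.1 x 0.1 degree rural box near 5.4 S, 16.6 E.
DEFAULT_BBOX = (16.55, -5.45, 16.65, -5.35)

#: Published per-metal censoring fractions (below LoD, below LoQ) out of 412
#: used to calibrate the default lognormal marginals.
CENSORING_TARGETS = {
    "As": (18 / 412, (18 + 148) / 412),
    "Hg": (140 / 412, (140 + 238) / 412),
    "Cd": (332 / 412, (332 + 76) / 412),
    "Pb": (358 / 412, (358 + 38) / 412),
}


def lognormal_params_from_censoring(
    lod: float, loq: float, p_below_lod: float, p_below_loq: float
) -> tuple[float, float]:
    """(mu, sigma) of a lognormal matching P(X < LoD) and P(X < LoQ).

    Solves the two Gaussian quantile equations
    ``Phi((ln lod - mu)/sigma) = p_below_lod`` and likewise for LoQ.
    """
    if not (0 < p_below_lod < p_below_loq < 1):
        raise ConfigurationError("need 0 < p_below_lod < p_below_loq < 1")
    z1, z2 = norm.ppf(p_below_lod), norm.ppf(p_below_loq)
    sigma = (np.log(loq) - np.log(lod)) / (z2 - z1)
    mu = np.log(lod) - sigma * z1
    return float(mu), float(sigma)


def lognormal_sigma_from_prevalence(median: float, threshold: float, prevalence: float) -> float:
    """Log-scale sigma such that P(X < threshold) = prevalence for a
    lognormal with the given median."""
    z = norm.ppf(prevalence)
    if z == 0:
        raise ConfigurationError("prevalence 0.5 leaves sigma unidentified")
    return float(np.log(threshold / median) / z)


def normal_sd_from_prevalence(mean: float, threshold: float, prevalence: float) -> float:
    """SD such that P(X < threshold) = prevalence for a normal with given mean."""
    z = norm.ppf(prevalence)
    if z == 0:
        raise ConfigurationError("prevalence 0.5 leaves sd unidentified")
    return float((threshold - mean) / z)


@dataclass(frozen=True)
class AnalyteSpec:
    """Lognormal marginal (log-scale mu/sigma) + detection limits for one metal."""

    name: str
    mu: float
    sigma: float
    limits: DetectionLimits

    @classmethod
    def from_censoring_targets(
        cls, limits: DetectionLimits, p_below_lod: float, p_below_loq: float
    ) -> "AnalyteSpec":
        mu, sigma = lognormal_params_from_censoring(
            limits.lod, limits.loq, p_below_lod, p_below_loq
        )
        return cls(limits.analyte, mu, sigma, limits)


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution + deficiency threshold for one covariate.

    ``dist`` is ``"normal"`` (loc = mean, scale = SD) or ``"lognormal"``
    (loc = log median, scale = log-scale sigma). ``deficient_below`` is the
    strict cut-off used downstream; ``unit`` is carried as metadata.
    """

    name: str
    dist: str
    loc: float
    scale: float
    unit: str = ""
    deficient_below: float | None = None

    def __post_init__(self):
        if self.dist not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown covariate distribution {self.dist!r}")
        if self.scale <= 0:
            raise ConfigurationError(f"{self.name}: scale must be > 0")

    @classmethod
    def normal(cls, name, mean, sd, unit="", deficient_below=None):
        return cls(name, "normal", float(mean), float(sd), unit, deficient_below)

    @classmethod
    def lognormal(cls, name, median, sigma, unit="", deficient_below=None):
        return cls(name, "lognormal", float(np.log(median)), float(sigma), unit, deficient_below)

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map a standard-normal field to this marginal."""
        if self.dist == "normal":
            return self.loc + self.scale * z
        return np.exp(self.loc + self.scale * z)


def default_analytes() -> dict[str, AnalyteSpec]:
    return {
        name: AnalyteSpec.from_censoring_targets(PUBLISHED_LIMITS[name], *CENSORING_TARGETS[name])
        for name in ("As", "Cd", "Hg", "Pb")
    }


def default_covariates() -> dict[str, CovariateSpec]:
    """Covariate marginals calibrated to published medians and deficiency
    prevalences (growth z-scores unitless; Se ug/L; Zn, Cu ug/dL; Hb g/dL)."""
    return {
        "haz": CovariateSpec.normal("haz", -2.1, normal_sd_from_prevalence(-2.1, -2.0, 0.553)),
        "whz": CovariateSpec.normal("whz", -0.5, normal_sd_from_prevalence(-0.5, -2.0, 0.107)),
        "waz": CovariateSpec.normal("waz", -1.5, normal_sd_from_prevalence(-1.5, -2.0, 0.340)),
        "se": CovariateSpec.lognormal(
            "se", 52.7, lognormal_sigma_from_prevalence(52.7, 70.0, 0.869),
            unit="ug/L", deficient_below=70.0,
        ),
        "zn": CovariateSpec.lognormal(
            "zn", 61.6, lognormal_sigma_from_prevalence(61.6, 65.0, 0.646),
            unit="ug/dL", deficient_below=65.0,
        ),
        "cu": CovariateSpec.lognormal(
            "cu", 145.0, lognormal_sigma_from_prevalence(145.0, 80.0, 0.015),
            unit="ug/dL", deficient_below=80.0,
        ),
        "hb": CovariateSpec.normal(
            "hb", 10.4, normal_sd_from_prevalence(10.4, 11.0, 0.680),
            unit="g/dL", deficient_below=11.0,
        ),
    }


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic cohort.

    ``cross_correlations`` maps (analyte, covariate) to the latent
    coregionalization rho in [-1, 1]; default +0.5 for (Hg, se) and -0.5
    for (As, zn), the two associations the analysis is designed to detect.
    ``spatial_range`` is the e-folding length (metres) of the exponential
    covariance C(d) = sill * exp(-d / range); ``cluster_dispersion_m`` the
    radius of the uniform disk children scatter in around their cluster
    centroid. ``micro_frac`` is the fraction of each log-field's variance
    carried by an individual-level (microscale + assay noise) component —
    serum biomarkers always vary person-to-person on top of any regional
    gradient, and without this component a single realisation's censoring
    fractions would be dominated by the random regional level.
    """

    n_children: int = 412
    n_clusters: int = 5
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    cluster_dispersion_m: float = 1200.0
    spatial_range: float = 2500.0
    sill: float = 1.0
    nugget: float = 1e-6
    micro_frac: float = 0.3
    cross_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("Hg", "se"): 0.5, ("As", "zn"): -0.5}
    )
    analytes: dict[str, AnalyteSpec] = field(default_factory=default_analytes)
    covariates: dict[str, CovariateSpec] = field(default_factory=default_covariates)
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters > self.n_children:
            raise ConfigurationError("n_clusters cannot exceed n_children")
        lon0, lat0, lon1, lat1 = self.bbox
        if not (lon1 > lon0 and lat1 > lat0):
            raise ConfigurationError(f"zero-area bbox {self.bbox!r}")
        if self.spatial_range <= 0:
            raise ConfigurationError("spatial_range must be > 0")
        if not 0.0 <= self.micro_frac < 1.0:
            raise ConfigurationError("micro_frac must lie in [0, 1)")
        for (a, c), rho in self.cross_correlations.items():
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError(f"rho({a},{c})={rho} outside [-1, 1]")
            if a not in self.analytes:
                raise ConfigurationError(f"cross-correlation names unknown analyte {a!r}")
            if c not in self.covariates:
                raise ConfigurationError(f"cross-correlation names unknown covariate {c!r}")

    # --- config file round-trip ----------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_children": self.n_children,
            "n_clusters": self.n_clusters,
            "bbox": list(self.bbox),
            "cluster_dispersion_m": self.cluster_dispersion_m,
            "spatial_range": self.spatial_range,
            "sill": self.sill,
            "nugget": self.nugget,
            "micro_frac": self.micro_frac,
            "seed": self.seed,
            "cross_correlations": [
                {"analyte": a, "covariate": c, "rho": r}
                for (a, c), r in self.cross_correlations.items()
            ],
            "analytes": {
                k: {"mu": v.mu, "sigma": v.sigma,
                    "lod": v.limits.lod, "loq": v.limits.loq, "toxic": v.limits.toxic}
                for k, v in self.analytes.items()
            },
            "covariates": {
                k: {"dist": v.dist, "loc": v.loc, "scale": v.scale,
                    "unit": v.unit, "deficient_below": v.deficient_below}
                for k, v in self.covariates.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        kw = dict(d)
        if "bbox" in kw:
            kw["bbox"] = tuple(kw["bbox"])
        if "cross_correlations" in kw:
            kw["cross_correlations"] = {
                (e["analyte"], e["covariate"]): float(e["rho"])
                for e in kw["cross_correlations"]
            }
        if "analytes" in kw:
            kw["analytes"] = {
                k: AnalyteSpec(k, v["mu"], v["sigma"],
                               DetectionLimits(k, v["lod"], v["loq"], v["toxic"]))
                for k, v in kw["analytes"].items()
            }
        if "covariates" in kw:
            kw["covariates"] = {
                k: CovariateSpec(k, v["dist"], v["loc"], v["scale"],
                                 v.get("unit", ""), v.get("deficient_below"))
                for k, v in kw["covariates"].items()
            }
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticCohort:
    """One simulated cohort: sites, latent truth, censored observations,
    covariates, and the config that produced them."""

    sites: pd.DataFrame  # child_id, cluster, lon, lat
    truth: pd.DataFrame  # child_id + one latent column per analyte (ug/L)
    observed: dict[str, CensoredSeries]
    covariates: pd.DataFrame  # child_id + covariate columns
    config: SimConfig

    @property
    def n(self) -> int:
        return len(self.sites)

    def coords(self) -> np.ndarray:
        return self.sites[["lon", "lat"]].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """One row per child: location, covariates, per-analyte category/value."""
        out = self.sites.merge(self.covariates, on="child_id")
        for name, series in self.observed.items():
            out[f"{name}_category"] = series.category
            out[f"{name}_value"] = series.values
        return out

    def sites_geojson(self) -> dict:
        feats = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(r.lon), float(r.lat)]},
                "properties": {"child_id": str(r.child_id), "cluster": int(r.cluster)},
            }
            for r in self.sites.itertuples()
        ]
        return {"type": "FeatureCollection", "features": feats}

    def write(self, outdir) -> dict[str, str]:
        """Write cohort CSV, truth CSV and sites GeoJSON; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cohort": str(outdir / "cohort.csv"),
            "truth": str(outdir / "truth.csv"),
            "sites": str(outdir / "sites.geojson"),
        }
        self.to_frame().to_csv(paths["cohort"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        with open(paths["sites"], "w") as fh:
            json.dump(self.sites_geojson(), fh)
        return paths


# ---------------------------------------------------------------------------
# site sampling


def sample_sites(config: SimConfig) -> pd.DataFrame:
    """Clustered site sampling: one centroid per cluster (uniform in an
    inset of the bbox) and children uniform in a disk of radius
    ``cluster_dispersion_m`` around their centroid, clipped to the bbox.

    Cluster sizes are as equal as possible (the first ``n mod k`` clusters
    take the extra child). Deterministic for a fixed config seed (stream:
    first spawn of the config's SeedSequence).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    lon0, lat0, lon1, lat1 = config.bbox
    n, k = config.n_children, config.n_clusters

    # keep centroids away from the edge by one dispersion radius where possible
    margin_lat = min(config.cluster_dispersion_m / 111_195.0, (lat1 - lat0) / 4)
    mid_lat = np.radians((lat0 + lat1) / 2)
    margin_lon = min(
        config.cluster_dispersion_m / (111_195.0 * max(np.cos(mid_lat), 1e-9)),
        (lon1 - lon0) / 4,
    )
    cent_lon = rng.uniform(lon0 + margin_lon, lon1 - margin_lon, size=k)
    cent_lat = rng.uniform(lat0 + margin_lat, lat1 - margin_lat, size=k)

    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    rows = []
    cid = 0
    for c in range(k):
        # uniform in disk: r = R * sqrt(u)
        r = config.cluster_dispersion_m * np.sqrt(rng.uniform(size=sizes[c]))
        theta = rng.uniform(0, 2 * np.pi, size=sizes[c])
        dlat = (r * np.cos(theta)) / 111_195.0
        dlon = (r * np.sin(theta)) / (111_195.0 * max(np.cos(np.radians(cent_lat[c])), 1e-9))
        lons = np.clip(cent_lon[c] + dlon, lon0, lon1)
        lats = np.clip(cent_lat[c] + dlat, lat0, lat1)
        for lo, la in zip(lons, lats):
            rows.append({"child_id": f"C{cid:04d}", "cluster": c, "lon": lo, "lat": la})
            cid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaussian random fields


def _field_factor(coords, spatial_range, sill, nugget) -> np.ndarray:
    """Lower Cholesky factor of the exponential covariance over sites,
    escalating the nugget jitter if needed."""
    D = pairwise_haversine(coords)
    C = sill * np.exp(-D / spatial_range)
    jitter = nugget * sill if nugget > 0 else 0.0
    for attempt in range(6):
        try:
            return cholesky(C + jitter * np.eye(len(C)), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter, 1e-12 * sill) * 10.0
    raise NumericalError(
        f"covariance not positive definite even with nugget jitter {jitter:.3e}"
    )


def simulate_bivariate_field(
    sites,
    spatial_range: float,
    sill: float,
    rho: float,
    seed: int | None = None,
    nugget: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Two cross-correlated Gaussian fields on the given lon/lat sites.

    Linear model of coregionalization: Z1 = Z_common and
    Z2 = rho * Z_common + sqrt(1 - rho^2) * Z_indep, each component a
    zero-mean field with covariance C(d) = sill * exp(-d / spatial_range).
    The pointwise correlation of (Z1, Z2) is rho; rho = 1 returns two
    identical vectors.
    """
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError(f"rho={rho} outside [-1, 1]")
    coords = np.asarray(sites, dtype=float)
    Lf = _field_factor(coords, spatial_range, sill, nugget)
    rng = np.random.default_rng(seed)
    z_common = Lf @ rng.standard_normal(len(coords))
    z_indep = Lf @ rng.standard_normal(len(coords))
    z2 = rho * z_common + np.sqrt(max(0.0, 1.0 - rho**2)) * z_indep
    return z_common, z2


def censor_observations(latent, limits: DetectionLimits) -> CensoredSeries:
    """Apply LoD/LoQ censoring to latent concentrations.

    Negative latent values (which the lognormal generator precludes but a
    custom config might not) are clamped to 0 with a warning before
    classification.
    """
    latent = np.asarray(latent, dtype=float)
    if np.any(latent < 0):
        warnings.warn(
            f"{limits.analyte}: {int(np.sum(latent < 0))} negative latent value(s) clamped to 0",
            stacklevel=2,
        )
        latent = np.clip(latent, 0.0, None)
    return classify(latent, limits)


# ---------------------------------------------------------------------------
# full cohort


def generate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort from a config.

    Streams off the config seed (SeedSequence spawns, in order): sites,
    then one per analyte field (config order), then one per covariate
    field. Analyte fields are standardized (unit marginal variance) and
    mapped through exp(mu + sigma z); covariate fields coregionalize with
    their paired analyte field where a cross-correlation is configured.
    """
    config = config or SimConfig()
    n_streams = 1 + len(config.analytes) + len(config.covariates)
    streams = np.random.SeedSequence(config.seed).spawn(n_streams)
    sites = sample_sites(config)
    coords = sites[["lon", "lat"]].to_numpy()
    n = len(coords)

    # one factor shared by every field (same sites, same covariance)
    Lf = _field_factor(coords, config.spatial_range, 1.0, config.nugget)
    w = config.micro_frac

    def mixed_field(rng: np.random.Generator) -> np.ndarray:
        """Spatial field + individual-level noise, standardized in-sample.

        Standardizing the realisation (an affine map, invisible to Lee's L
        and every rank statistic) pins the censoring fractions and
        deficiency prevalences of *this* cohort to their configured
        targets instead of letting the random regional level shift them.
        """
        z = np.sqrt(1.0 - w) * (Lf @ rng.standard_normal(n)) + np.sqrt(w) * rng.standard_normal(n)
        return (z - z.mean()) / z.std()

    pair_of = {cov: (an, rho) for (an, cov), rho in config.cross_correlations.items()}

    analyte_fields: dict[str, np.ndarray] = {}
    truth = pd.DataFrame({"child_id": sites["child_id"]})
    observed: dict[str, CensoredSeries] = {}
    for i, (name, spec) in enumerate(config.analytes.items()):
        z = mixed_field(np.random.default_rng(streams[1 + i]))
        analyte_fields[name] = z
        latent = np.exp(spec.mu + spec.sigma * z)
        truth[name] = latent
        observed[name] = censor_observations(latent, spec.limits)

    covariates = pd.DataFrame({"child_id": sites["child_id"]})
    offset = 1 + len(config.analytes)
    for j, (name, spec) in enumerate(config.covariates.items()):
        z_ind = mixed_field(np.random.default_rng(streams[offset + j]))
        if name in pair_of:
            an, rho = pair_of[name]
            z = rho * analyte_fields[an] + np.sqrt(max(0.0, 1.0 - rho**2)) * z_ind
            z = (z - z.mean()) / z.std()
        else:
            z = z_ind
        covariates[name] = spec.transform(z)

    return SyntheticCohort(sites, truth, observed, covariates, config)
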