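"""Synthetic biogeographies for testing and calibration experiments.

A :class:`TrueWorld` holds ground-truth occurrence-probability fields over
a lat/lon domain: *endemic* taxa are Gaussian bumps (baseline + peak at a
center, decaying with great-circle distance at scale ``range_sigma`` km;
optionally two bumps to exercise non-convex prediction regions) and
*cosmopolitan* taxa are spatially constant. Samples are Bernoulli draws
from these fields at uniform (or clustered, or user-supplied) locations.
The world also serves as an oracle predictor — the Bayes inversion run on
the true fields instead of estimates — giving a performance ceiling for
any fitted atlas.

Defaults (range_sigma log-uniform 100-600 km, peaks 0.3-0.9, baselines
0-0.05, continental-U.S. extent) yield the heavy right skew of taxon
prevalence and the endemic/cosmopolitan mix that make geolocation from
presence/absence possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .geometry import BoundingBox, GeoCoordinate, SpatialGrid, haversine_km
from .prediction import OriginPrediction, QuerySample, predict_origin
from .smoothing import (
    CONSTANT_SURFACE_RHO,
    FitConfig,
    OccurrenceAtlas,
    OccurrenceSurface,
    SampleTable,
)

__all__ = [
    "SpeciesField",
    "TrueWorld",
    "DEFAULT_DOMAIN",
    "make_world",
    "true_probability",
    "simulate_samples",
    "oracle_predict",
    "world_atlas",
]

#: Approximate continental-U.S. extent (purely conventional default domain).
DEFAULT_DOMAIN = BoundingBox(lat_min=24.0, lat_max=50.0, lon_min=-125.0, lon_max=-67.0)


@dataclass(frozen=True)
class SpeciesField:
    """Ground-truth occurrence field for one taxon.

    kind "endemic": baseline + (peak-baseline)*max_over_centers
    exp(-d(t, center)^2 / (2 sigma^2)); kind "cosmopolitan": constant peak.
    """

    taxon_id: str
    kind: str  # "endemic" | "cosmopolitan"
    centers: tuple[GeoCoordinate, ...]
    range_sigma: float
    peak: float
    baseline: float

    def __post_init__(self) -> None:
        if self.kind not in ("endemic", "cosmopolitan"):
            raise InvalidInputError(f"unknown species kind {self.kind!r}")
        if not 0.0 <= self.baseline <= self.peak <= 1.0:
            raise InvalidInputError("need 0 <= baseline <= peak <= 1")
        if self.kind == "endemic":
            if self.range_sigma <= 0:
                raise InvalidInputError("endemic species need range_sigma > 0")
            if not self.centers:
                raise InvalidInputError("endemic species need at least one center")


@dataclass
class TrueWorld:
    domain: BoundingBox
    species: list[SpeciesField]
    seed: int

    @property
    def taxon_ids(self) -> list[str]:
        return [sp.taxon_id for sp in self.species]

    def prob_matrix(self, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
        """(len(lats), m) matrix of true occurrence probabilities."""
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        P = np.empty((lats.size, len(self.species)))
        for j, sp in enumerate(self.species):
            P[:, j] = _field_values(sp, lats, lons)
        return P

    # -- JSON persistence (for `simulate` CLI round trips)

    def to_json(self, path) -> None:
        payload = {
            "domain": [self.domain.lat_min, self.domain.lat_max,
                       self.domain.lon_min, self.domain.lon_max],
            "seed": self.seed,
            "species": [
                {
                    "taxon_id": sp.taxon_id,
                    "kind": sp.kind,
                    "centers": [[c.lat, c.lon] for c in sp.centers],
                    "range_sigma": sp.range_sigma,
                    "peak": sp.peak,
                    "baseline": sp.baseline,
                }
                for sp in self.species
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TrueWorld":
        d = json.loads(Path(path).read_text())
        return cls(
            domain=BoundingBox(*d["domain"]),
            seed=int(d["seed"]),
            species=[
                SpeciesField(
                    taxon_id=s["taxon_id"],
                    kind=s["kind"],
                    centers=tuple(GeoCoordinate(la, lo) for la, lo in s["centers"]),
                    range_sigma=float(s["range_sigma"]),
                    peak=float(s["peak"]),
                    baseline=float(s["baseline"]),
                )
                for s in d["species"]
            ],
        )


def _field_values(sp: SpeciesField, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    if sp.kind == "cosmopolitan":
        return np.full(lats.size, sp.peak)
    best = np.zeros(lats.size)
    for c in sp.centers:
        d = haversine_km(lats, lons, c.lat, c.lon)
        np.maximum(best, np.exp(-(d * d) / (2.0 * sp.range_sigma**2)), out=best)
    return sp.baseline + (sp.peak - sp.baseline) * best


def true_probability(world: TrueWorld, taxon_id: str, location: GeoCoordinate) -> float:
    """True occurrence probability of one taxon at one location."""
    for sp in world.species:
        if sp.taxon_id == taxon_id:
            return float(
                _field_values(sp, np.array([location.lat]), np.array([location.lon]))[0]
            )
    raise KeyError(f"unknown taxon {taxon_id!r}")


def make_world(
    m: int,
    endemic_fraction: float = 0.7,
    domain: BoundingBox = DEFAULT_DOMAIN,
    seed: int = 0,
    sigma_range_km: tuple[float, float] = (100.0, 600.0),
    peak_range: tuple[float, float] = (0.3, 0.9),
    baseline_range: tuple[float, float] = (0.0, 0.05),
    two_bump_fraction: float = 0.0,
) -> TrueWorld:
    """Draw a random ground-truth biogeography.

    Centers are uniform over the domain; range_sigma is log-uniform over
    ``sigma_range_km``; peaks and baselines uniform over their ranges. A
    ``two_bump_fraction`` of the endemic taxa get a second center, giving
    non-convex high-probability regions.
    """
    if m < 1:
        raise InvalidInputError("need m >= 1 taxa")
    if not 0.0 <= endemic_fraction <= 1.0:
        raise InvalidInputError("endemic_fraction must lie in [0, 1]")
    if not 0.0 <= two_bump_fraction <= 1.0:
        raise InvalidInputError("two_bump_fraction must lie in [0, 1]")
    if sigma_range_km[0] <= 0 or sigma_range_km[0] > sigma_range_km[1]:
        raise InvalidInputError("invalid sigma range")
    for lo, hi in (peak_range, baseline_range):
        if not 0.0 <= lo <= hi <= 1.0:
            raise InvalidInputError("peak/baseline ranges must be within [0, 1]")

    rng = np.random.default_rng(seed)
    n_endemic = int(round(m * endemic_fraction))
    width = len(str(max(m - 1, 1)))
    species: list[SpeciesField] = []
    for j in range(m):
        taxon_id = f"taxon_{j:0{width}d}"
        peak = float(rng.uniform(*peak_range))
        if j < n_endemic:
            n_centers = 2 if rng.uniform() < two_bump_fraction else 1
            centers = tuple(
                GeoCoordinate(
                    float(rng.uniform(domain.lat_min, domain.lat_max)),
                    float(rng.uniform(domain.lon_min, domain.lon_max)),
                )
                for _ in range(n_centers)
            )
            sigma = float(
                np.exp(rng.uniform(np.log(sigma_range_km[0]), np.log(sigma_range_km[1])))
            )
            baseline = float(rng.uniform(*baseline_range))
            baseline = min(baseline, peak)
            species.append(
                SpeciesField(taxon_id, "endemic", centers, sigma, peak, baseline)
            )
        else:
            species.append(
                SpeciesField(taxon_id, "cosmopolitan", (), 0.0, peak, peak)
            )
    return TrueWorld(domain=domain, species=species, seed=seed)


def simulate_samples(
    world: TrueWorld,
    n: int,
    seed: int = 0,
    locations: Sequence[GeoCoordinate] | None = None,
    n_clusters: int = 0,
    cluster_sigma_km: float = 150.0,
) -> SampleTable:
    """Draw n geo-referenced presence/absence samples from a world.

    Locations are uniform over the domain by default; pass ``locations``
    to fix them, or ``n_clusters`` > 0 for a mixture of Gaussians around
    random "cities" (reproducing sampling-intensity effects).
    """
    if n < 1:
        raise InvalidInputError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    dom = world.domain
    if locations is not None:
        if len(locations) != n:
            raise InvalidInputError("len(locations) must equal n")
        lats = np.array([c.lat for c in locations])
        lons = np.array([c.lon for c in locations])
    elif n_clusters > 0:
        centers_lat = rng.uniform(dom.lat_min, dom.lat_max, n_clusters)
        centers_lon = rng.uniform(dom.lon_min, dom.lon_max, n_clusters)
        which = rng.integers(0, n_clusters, n)
        sigma_deg = cluster_sigma_km / 111.195  # ~km per degree latitude
        lats = centers_lat[which] + rng.normal(0.0, sigma_deg, n)
        lons = centers_lon[which] + rng.normal(0.0, sigma_deg, n)
        lats = np.clip(lats, dom.lat_min, dom.lat_max)
        lons = np.clip(lons, dom.lon_min, dom.lon_max)
    else:
        lats = rng.uniform(dom.lat_min, dom.lat_max, n)
        lons = rng.uniform(dom.lon_min, dom.lon_max, n)

    P = world.prob_matrix(lats, lons)
    Y = (rng.uniform(size=P.shape) < P).astype(np.int8)
    width = len(str(max(n - 1, 1)))
    return SampleTable(
        sample_ids=[f"sample_{i:0{width}d}" for i in range(n)],
        lats=lats,
        lons=lons,
        taxon_ids=world.taxon_ids,
        Y=Y,
    )


def world_atlas(
    world: TrueWorld, grid: SpatialGrid, clip_epsilon: float = 1e-6
) -> OccurrenceAtlas:
    """An atlas whose surfaces are the *true* fields (oracle model)."""
    P = world.prob_matrix(grid.lats, grid.lons)
    surfaces = [
        OccurrenceSurface(
            taxon_id=sp.taxon_id,
            rho=sp.range_sigma if sp.kind == "endemic" else CONSTANT_SURFACE_RHO,
            probs=P[:, j],
        )
        for j, sp in enumerate(world.species)
    ]
    return OccurrenceAtlas(
        grid=grid,
        surfaces=surfaces,
        taxon_ids=world.taxon_ids,
        fit_config=FitConfig(clip_epsilon=clip_epsilon),
    )


def oracle_predict(
    world: TrueWorld,
    query: QuerySample,
    grid: SpatialGrid,
    thresholds=None,
    clip_epsilon: float = 1e-6,
) -> OriginPrediction:
    """Bayes inversion using the true occurrence fields (performance ceiling)."""
    return predict_origin(world_atlas(world, grid, clip_epsilon), query, thresholds)
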