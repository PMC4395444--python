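"""Kernel-smoothed occurrence-probability surfaces with GCV bandwidths.

For each taxon j the occurrence probability over the grid is the
Nadaraya-Watson estimator

    p_j(t) = sum_i w_ij(t) Y_ij,   w_ij(t) = k_j(d(t, s_i)) / sum_l k_j(d(t, s_l)),

with Gaussian kernel k_j(h) = exp(-h^2 / (2 rho_j^2)) on great-circle
distance h (km). The bandwidth rho_j is selected per taxon by generalized
cross-validation of the linear smoother W_rho (self-weight retained):

    GCV(rho) = (1/n) ||W_rho y_j - y_j||^2 / (1 - tr(W_rho)/n)^2.

As rho -> 0, W_rho -> I and the criterion degenerates to 0/0; candidates
whose trace ratio reaches ``max_trace_ratio`` are excluded from selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    BandwidthSelectionError,
    FitError,
    InvalidInputError,
)
from .geometry import GeoCoordinate, SpatialGrid, pairwise_distances

__all__ = [
    "SampleTable",
    "FitConfig",
    "WeightVector",
    "GCVDiagnostics",
    "OccurrenceSurface",
    "OccurrenceAtlas",
    "kernel_weights",
    "smooth_occurrence",
    "gcv_score",
    "select_bandwidth",
    "fit_atlas",
    "default_bandwidth_candidates",
]

#: Sentinel bandwidth for taxa that were not smoothed (constant surfaces).
CONSTANT_SURFACE_RHO = float("nan")


def default_bandwidth_candidates(
    low_km: float = 10.0, high_km: float = 3000.0, num: int = 25
) -> np.ndarray:
    """Log-spaced bandwidth search grid spanning city to continental scales."""
    return np.geomspace(low_km, high_km, num)


@dataclass
class FitConfig:
    """Tunable knobs of atlas fitting.

    bandwidth_candidates
        Ascending positive bandwidths (km) searched by GCV per taxon.
    clip_epsilon
        Probabilities are clipped to [eps, 1-eps] before entering the
        log-likelihood, keeping every grid cell comparable.
    max_trace_ratio
        Candidates with tr(W_rho)/n at or above this are degenerate
        (near-interpolating smoother) and excluded from selection.
    min_prevalence
        A taxon needs at least this many presences *and* absences in
        training to be smoothed; otherwise it gets a constant surface
        equal to its prevalence fraction.
    """

    bandwidth_candidates: np.ndarray = field(default_factory=default_bandwidth_candidates)
    clip_epsilon: float = 0.03
    max_trace_ratio: float = 0.5
    min_prevalence: int = 1

    def __post_init__(self) -> None:
        cand = np.asarray(self.bandwidth_candidates, dtype=float)
        if cand.size == 0 or np.any(cand <= 0) or np.any(np.diff(cand) <= 0):
            raise InvalidInputError("bandwidth candidates must be ascending and > 0")
        self.bandwidth_candidates = cand
        if not 0 < self.clip_epsilon < 0.5:
            raise InvalidInputError("clip_epsilon must lie in (0, 0.5)")
        if not 0 < self.max_trace_ratio < 1:
            raise InvalidInputError("max_trace_ratio must lie in (0, 1)")
        if self.min_prevalence < 0:
            raise InvalidInputError("min_prevalence must be >= 0")

    def to_dict(self) -> dict:
        return {
            "bandwidth_candidates": [float(r) for r in self.bandwidth_candidates],
            "clip_epsilon": self.clip_epsilon,
            "max_trace_ratio": self.max_trace_ratio,
            "min_prevalence": self.min_prevalence,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitConfig":
        return cls(
            bandwidth_candidates=np.asarray(d["bandwidth_candidates"], dtype=float),
            clip_epsilon=float(d["clip_epsilon"]),
            max_trace_ratio=float(d["max_trace_ratio"]),
            min_prevalence=int(d["min_prevalence"]),
        )


@dataclass
class SampleTable:
    """Geo-referenced binary occurrence matrix: n samples by m taxa."""

    sample_ids: list[str]
    lats: np.ndarray
    lons: np.ndarray
    taxon_ids: list[str]
    Y: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.Y = np.asarray(self.Y)
        n, m = self.Y.shape
        if n < 1 or m < 1:
            raise InvalidInputError("need at least one sample and one taxon")
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise InvalidInputError("sample_ids must be unique and match Y rows")
        if len(self.taxon_ids) != m or len(set(self.taxon_ids)) != m:
            raise InvalidInputError("taxon_ids must be unique and match Y columns")
        if self.lats.shape != (n,) or self.lons.shape != (n,):
            raise InvalidInputError("one coordinate pair required per sample")
        if not (np.isfinite(self.lats).all() and np.isfinite(self.lons).all()):
            raise InvalidInputError("coordinates must be finite")
        if not np.isin(self.Y, (0, 1)).all():
            raise InvalidInputError("Y entries must be exactly 0 or 1")
        self.Y = self.Y.astype(np.int8, copy=False)

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.Y.shape[1]

    @property
    def locations(self) -> list[GeoCoordinate]:
        return [GeoCoordinate(la, lo) for la, lo in zip(self.lats, self.lons)]

    def subset(self, indices: Sequence[int]) -> "SampleTable":
        idx = np.asarray(indices, dtype=int)
        cov = self.covariates.iloc[idx].reset_index(drop=True) if self.covariates is not None else None
        return SampleTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            lats=self.lats[idx],
            lons=self.lons[idx],
            taxon_ids=list(self.taxon_ids),
            Y=self.Y[idx],
            covariates=cov,
        )

    def richness(self) -> np.ndarray:
        """Per-sample taxon count."""
        return self.Y.sum(axis=1)


@dataclass
class WeightVector:
    """Normalized kernel weights of the training samples at one target point."""

    weights: np.ndarray
    target: GeoCoordinate
    rho: float
    underflow: bool = False  # every kernel value underflowed; nearest point mass used


@dataclass
class GCVDiagnostics:
    rho: float
    score: float
    trace_ratio: float
    rss: float
    degenerate: bool = False


@dataclass
class OccurrenceSurface:
    """One taxon's smoothed occurrence probabilities over the grid.

    ``rho`` is NaN for taxa that failed the prevalence filter and carry a
    constant surface equal to their observed prevalence fraction.
    """

    taxon_id: str
    rho: float
    probs: np.ndarray
    prevalence: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise InvalidInputError(f"surface for {self.taxon_id} outside [0, 1]")
        if not math.isnan(self.rho) and self.rho <= 0:
            raise InvalidInputError("bandwidth must be positive (or NaN sentinel)")


# ---------------------------------------------------------------------------
# kernel machinery


def _kernel_rows(D: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized Gaussian kernel weights for a distance matrix (km).

    Rows where every kernel value underflows to zero fall back to a point
    mass on the nearest source (lowest index on ties). Returns the weight
    matrix and a boolean vector flagging fallback rows.
    """
    K = np.exp(-(D * D) / (2.0 * rho * rho))
    rowsum = K.sum(axis=1)
    dead = rowsum == 0.0
    if dead.any():
        K[dead] = 0.0
        nearest = np.argmin(D[dead], axis=1)
        K[np.nonzero(dead)[0], nearest] = 1.0
        rowsum = K.sum(axis=1)
    return K / rowsum[:, None], dead


def kernel_weights(
    target: GeoCoordinate, sources: Sequence[GeoCoordinate], rho: float
) -> WeightVector:
    """Normalized Gaussian kernel weights of ``sources`` at ``target``."""
    if len(sources) == 0:
        raise InvalidInputError("need at least one source location")
    if rho <= 0:
        raise InvalidInputError("bandwidth rho must be > 0")
    s_lats = np.array([s.lat for s in sources])
    s_lons = np.array([s.lon for s in sources])
    D = pairwise_distances(np.array([target.lat]), np.array([target.lon]), s_lats, s_lons)
    W, dead = _kernel_rows(D, rho)
    return WeightVector(weights=W[0], target=target, rho=rho, underflow=bool(dead[0]))


def smooth_occurrence(
    presence: np.ndarray,
    sources: Sequence[GeoCoordinate],
    rho: float,
    grid: SpatialGrid,
) -> OccurrenceSurface:
    """Smooth one taxon's presence/absence vector onto the grid (single-taxon Eq.)."""
    y = np.asarray(presence, dtype=float)
    if y.shape != (len(sources),):
        raise InvalidInputError("presence length must match number of sources")
    s_lats = np.array([s.lat for s in sources])
    s_lons = np.array([s.lon for s in sources])
    D = pairwise_distances(grid.lats, grid.lons, s_lats, s_lons)
    W, _ = _kernel_rows(D, rho)
    probs = np.clip(W @ y, 0.0, 1.0)
    return OccurrenceSurface(
        taxon_id="", rho=float(rho), probs=probs, prevalence=int(np.sum(y))
    )


def gcv_score(
    presence: np.ndarray,
    sources: Sequence[GeoCoordinate],
    rho: float,
    max_trace_ratio: float = 0.99,
) -> GCVDiagnostics:
    """Generalized cross-validation score of one bandwidth for one taxon."""
    y = np.asarray(presence, dtype=float)
    n = y.size
    if n < 2:
        raise InvalidInputError("GCV needs at least two samples")
    if rho <= 0:
        raise InvalidInputError("bandwidth rho must be > 0")
    s_lats = np.array([s.lat for s in sources])
    s_lons = np.array([s.lon for s in sources])
    D = pairwise_distances(s_lats, s_lons, s_lats, s_lons)
    W, _ = _kernel_rows(D, rho)
    trace_ratio = float(np.trace(W) / n)
    resid = W @ y - y
    rss = float(np.mean(resid * resid))
    degenerate = trace_ratio >= max_trace_ratio
    score = math.inf if trace_ratio >= 1.0 else rss / (1.0 - trace_ratio) ** 2
    return GCVDiagnostics(
        rho=float(rho), score=score, trace_ratio=trace_ratio, rss=rss, degenerate=degenerate
    )


def select_bandwidth(
    presence: np.ndarray,
    sources: Sequence[GeoCoordinate],
    config: FitConfig,
    taxon_id: str = "",
) -> tuple[float, list[GCVDiagnostics]]:
    """GCV-minimizing bandwidth among non-degenerate candidates.

    Ties are broken toward the *larger* bandwidth (smoother surface).
    """
    diagnostics = [
        gcv_score(presence, sources, rho, config.max_trace_ratio)
        for rho in config.bandwidth_candidates
    ]
    best: GCVDiagnostics | None = None
    for d in diagnostics:  # candidates ascend, so <= keeps the largest tied rho
        if d.degenerate:
            continue
        if best is None or d.score <= best.score:
            best = d
    if best is None:
        raise BandwidthSelectionError(
            f"all bandwidth candidates degenerate for taxon {taxon_id!r}"
        )
    return best.rho, diagnostics


# ---------------------------------------------------------------------------
# atlas


@dataclass
class OccurrenceAtlas:
    """The fitted model: one smoothed surface (and bandwidth) per taxon."""

    grid: SpatialGrid
    surfaces: list[OccurrenceSurface]
    taxon_ids: list[str]
    fit_config: FitConfig

    def __post_init__(self) -> None:
        if len(self.surfaces) != len(self.taxon_ids):
            raise InvalidInputError("one surface required per taxon")
        n = self.grid.n_cells
        for s in self.surfaces:
            if s.probs.shape != (n,):
                raise AlignmentError(
                    f"surface {s.taxon_id} has {s.probs.size} cells, grid has {n}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def prob_matrix(self) -> np.ndarray:
        """(N cells, m taxa) matrix of smoothed probabilities."""
        if not self.surfaces:
            return np.zeros((self.grid.n_cells, 0))
        return np.column_stack([s.probs for s in self.surfaces])

    # -- persistence (plain-text; round-trips float64 bit-exactly via %.17g)

    def save(self, directory) -> None:
        d = Path(directory)
        (d / "surfaces").mkdir(parents=True, exist_ok=True)
        self.grid.to_csv(d / "grid.csv")
        pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                "rho_km": [s.rho for s in self.surfaces],
                "prevalence": [s.prevalence for s in self.surfaces],
            }
        ).to_csv(d / "taxa.csv", index=False, float_format="%.17g")
        meta = {
            "fit_config": self.fit_config.to_dict(),
            "cell_height_km": self.grid.cell_height_km,
            "cell_width_km": self.grid.cell_width_km,
            "grid_provenance": {
                k: v for k, v in self.grid.provenance.items() if k != "mask"
            },
        }
        (d / "atlas.json").write_text(json.dumps(meta, indent=1))
        for i, s in enumerate(self.surfaces):
            np.savetxt(d / "surfaces" / f"surface_{i:06d}.txt", s.probs, fmt="%.17g")

    @classmethod
    def load(cls, directory) -> "OccurrenceAtlas":
        d = Path(directory)
        meta = json.loads((d / "atlas.json").read_text())
        grid = SpatialGrid.from_csv(
            d / "grid.csv",
            cell_height_km=meta["cell_height_km"],
            cell_width_km=meta["cell_width_km"],
        )
        grid.provenance = meta.get("grid_provenance", {})
        taxa = pd.read_csv(d / "taxa.csv")
        surfaces = []
        for i, row in taxa.iterrows():
            probs = np.loadtxt(d / "surfaces" / f"surface_{i:06d}.txt", ndmin=1)
            surfaces.append(
                OccurrenceSurface(
                    taxon_id=str(row["taxon_id"]),
                    rho=float(row["rho_km"]),
                    probs=probs,
                    prevalence=int(row["prevalence"]),
                )
            )
        return cls(
            grid=grid,
            surfaces=surfaces,
            taxon_ids=[str(t) for t in taxa["taxon_id"]],
            fit_config=FitConfig.from_dict(meta["fit_config"]),
        )


def fit_atlas(
    samples: SampleTable, grid: SpatialGrid, config: FitConfig | None = None
) -> OccurrenceAtlas:
    """Fit one smoothed surface per taxon, selecting bandwidths by GCV.

    Vectorized across taxa: the smoother matrix W_rho depends only on the
    sample layout and the candidate bandwidth, so each candidate's fitted
    values for *all* taxa come from one matrix product. Taxa failing the
    prevalence filter (fewer than ``min_prevalence`` presences or absences)
    get a constant surface at their prevalence fraction with a NaN
    bandwidth sentinel, so query vectors never need re-indexing.
    """
    config = config or FitConfig()
    n, m = samples.n_samples, samples.n_taxa
    if m == 0:
        raise FitError("no taxa to fit")
    Y = samples.Y.astype(float)
    counts = Y.sum(axis=0)
    smooth_mask = (counts >= config.min_prevalence) & (counts <= n - config.min_prevalence)

    rho_selected = np.full(m, CONSTANT_SURFACE_RHO)
    cand_index = np.full(m, -1, dtype=int)

    if smooth_mask.any() and n >= 2:
        Ys = Y[:, smooth_mask]
        D = pairwise_distances(samples.lats, samples.lons, samples.lats, samples.lons)
        candidates = config.bandwidth_candidates
        scores = np.full((candidates.size, Ys.shape[1]), np.inf)
        valid = np.zeros(candidates.size, dtype=bool)
        for c, rho in enumerate(candidates):
            W, _ = _kernel_rows(D, rho)
            trace_ratio = np.trace(W) / n
            if trace_ratio >= config.max_trace_ratio:
                continue
            valid[c] = True
            resid = W @ Ys - Ys
            rss = np.mean(resid * resid, axis=0)
            scores[c] = rss / (1.0 - trace_ratio) ** 2
        if not valid.any():
            raise BandwidthSelectionError("all bandwidth candidates degenerate")
        # argmin over valid candidates; ties broken toward the larger rho
        masked = np.where(valid[:, None], scores, np.inf)
        rev = masked[::-1]
        pick = candidates.size - 1 - np.argmin(rev, axis=0)
        cand_index[smooth_mask] = pick
        rho_selected[smooth_mask] = candidates[pick]
    elif smooth_mask.any() and n < 2:
        # single sample: GCV undefined; a lone observation pins every taxon
        # at its own value, i.e. a constant surface
        smooth_mask[:] = False

    probs = np.empty((grid.n_cells, m))
    const_mask = ~smooth_mask
    if const_mask.any():
        probs[:, const_mask] = (counts[const_mask] / n)[None, :]
    if smooth_mask.any():
        Dg = pairwise_distances(grid.lats, grid.lons, samples.lats, samples.lons)
        for c in np.unique(cand_index[smooth_mask]):
            sel = cand_index == c
            Wg, _ = _kernel_rows(Dg, config.bandwidth_candidates[c])
            probs[:, sel] = Wg @ Y[:, sel]
    np.clip(probs, 0.0, 1.0, out=probs)

    surfaces = [
        OccurrenceSurface(
            taxon_id=samples.taxon_ids[j],
            rho=float(rho_selected[j]),
            probs=probs[:, j],
            prevalence=int(counts[j]),
        )
        for j in range(m)
    ]
    return OccurrenceAtlas(
        grid=grid,
        surfaces=surfaces,
        taxon_ids=list(samples.taxon_ids),
        fit_config=replace(config),
    )
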