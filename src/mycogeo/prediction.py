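"""Origin prediction by Bayes-rule inversion of an occurrence atlas.

Under a flat prior over grid cells, the posterior of a query sample's
origin is proportional to the Bernoulli likelihood of its presence/absence
vector under the per-taxon smoothed probabilities. The point estimate is
the argmax cell; normalizing the likelihood over cells gives a predictive
pmf, which is thresholded into highest-density prediction regions whose
mass threshold q is calibrated on held-out (subtesting) data so regions
achieve their nominal coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AlignmentError, CalibrationError, InvalidInputError
from .geometry import GeoCoordinate
from .smoothing import OccurrenceAtlas, SampleTable

__all__ = [
    "QuerySample",
    "OriginPrediction",
    "ThresholdCalibration",
    "CalibrationResult",
    "log_likelihood_field",
    "predictive_pmf",
    "prediction_region",
    "predict_origin",
    "calibrate_threshold",
    "minimal_covering_mass",
]


@dataclass
class QuerySample:
    """A sample of unknown origin: binary taxon vector aligned to an atlas."""

    query_id: str
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if not np.isin(self.presence, (0, 1)).all():
            raise InvalidInputError("query presence entries must be 0 or 1")
        self.presence = self.presence.astype(np.int8, copy=False)


@dataclass
class OriginPrediction:
    """Full inferential output for one query."""

    query_id: str
    s_hat: GeoCoordinate
    argmax_cell: int
    loglik: np.ndarray
    pmf: np.ndarray
    regions: dict[float, np.ndarray] = field(default_factory=dict)
    thresholds: dict[float, float] = field(default_factory=dict)


def _clipped_log_probs(atlas: OccurrenceAtlas) -> tuple[np.ndarray, np.ndarray]:
    eps = atlas.fit_config.clip_epsilon
    P = np.clip(atlas.prob_matrix(), eps, 1.0 - eps)
    return np.log(P), np.log1p(-P)


def log_likelihood_field(atlas: OccurrenceAtlas, query: QuerySample) -> np.ndarray:
    """Per-cell Bernoulli log-likelihood of the query's presence vector.

    Surfaces are clipped to [eps, 1-eps] so improbable cells are penalized
    rather than excluded; the field is always finite.
    """
    y = query.presence
    if y.shape != (atlas.n_taxa,):
        raise AlignmentError(
            f"query has {y.size} taxa but atlas has {atlas.n_taxa}"
        )
    if atlas.n_taxa == 0:
        return np.zeros(atlas.grid.n_cells)
    logP, log1mP = _clipped_log_probs(atlas)
    yf = y.astype(float)
    return logP @ yf + log1mP @ (1.0 - yf)


def predictive_pmf(loglik: np.ndarray) -> np.ndarray:
    """Normalize a log-likelihood field into a pmf over grid cells.

    Computed stably as softmax with max subtraction; invariant to adding a
    constant to the field.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.size == 0 or not np.isfinite(ll).all():
        raise InvalidInputError("log-likelihood field must be finite and non-empty")
    w = np.exp(ll - ll.max())
    return w / w.sum()


def _hdr_order(pmf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stable descending order of cells and the cumulative mass along it."""
    order = np.argsort(-pmf, kind="stable")  # ties by ascending cell index
    return order, np.cumsum(pmf[order])


def prediction_region(pmf: np.ndarray, q: float) -> np.ndarray:
    """Highest-density region: fewest cells whose mass reaches q.

    Cells are accumulated in descending pmf order until the cumulative mass
    first reaches q; all cells tied with the last included value are also
    included (so the region is order-independent). q = 0 gives the empty
    set; zero-mass cells are never included. Returns sorted cell indices.
    """
    pmf = np.asarray(pmf, dtype=float)
    if not 0.0 <= q <= 1.0:
        raise InvalidInputError("q must lie in [0, 1]")
    if q <= 0.0:
        return np.empty(0, dtype=int)
    order, cum = _hdr_order(pmf)
    k = int(np.searchsorted(cum, q, side="left"))
    if k >= order.size:  # rounding left total slightly below q
        k = order.size - 1
    v_stop = pmf[order[k]]
    members = (pmf >= v_stop) & (pmf > 0.0)
    return np.nonzero(members)[0]


def predict_origin(
    atlas: OccurrenceAtlas,
    query: QuerySample,
    thresholds: Mapping[float, float] | None = None,
    log_prior: np.ndarray | None = None,
) -> OriginPrediction:
    """Point estimate (argmax cell) plus pmf and optional prediction regions.

    ``thresholds`` maps nominal coverage level -> calibrated mass q (from
    :func:`calibrate_threshold`). ``log_prior`` optionally replaces the flat
    prior with per-cell log-weights added to the field.
    """
    loglik = log_likelihood_field(atlas, query)
    if log_prior is not None:
        log_prior = np.asarray(log_prior, dtype=float)
        if log_prior.shape != loglik.shape:
            raise AlignmentError("log_prior length must match the grid")
        loglik = loglik + log_prior
    argmax_cell = int(np.argmax(loglik))  # ties to lowest index
    pmf = predictive_pmf(loglik)
    regions: dict[float, np.ndarray] = {}
    thresholds = dict(thresholds or {})
    for level, q in thresholds.items():
        regions[level] = prediction_region(pmf, q)
    return OriginPrediction(
        query_id=query.query_id,
        s_hat=atlas.grid.coordinate(argmax_cell),
        argmax_cell=argmax_cell,
        loglik=loglik,
        pmf=pmf,
        regions=regions,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# coverage calibration


def minimal_covering_mass(pmf: np.ndarray, true_cell: int) -> float:
    """Smallest mass threshold strictly above which the HDR covers ``true_cell``.

    Equals the cumulative pmf of cells ranked strictly before the true
    cell's tie group in the stable HDR ordering: ``true_cell`` is in
    ``prediction_region(pmf, q)`` iff ``q > minimal_covering_mass`` (and
    q > 0). Returns +inf for a zero-mass true cell, which no region covers.
    """
    pmf = np.asarray(pmf, dtype=float)
    v = pmf[true_cell]
    if v <= 0.0:
        return float("inf")
    return float(pmf[pmf > v].sum())


@dataclass
class ThresholdCalibration:
    level: float  # nominal coverage 1 - alpha
    q: float
    achieved_coverage: float


@dataclass
class CalibrationResult:
    levels: dict[float, ThresholdCalibration]
    n_calibration: int

    def thresholds(self) -> dict[float, float]:
        return {lvl: cal.q for lvl, cal in self.levels.items()}


def calibrate_threshold(
    atlas: OccurrenceAtlas,
    calibration: SampleTable,
    levels: Sequence[float] = (0.5, 0.75, 0.9),
    coarse_step: float = 0.01,
    fine_step: float = 0.001,
) -> CalibrationResult:
    """Choose the mass threshold q achieving nominal coverage on held-out data.

    For each held-out sample the predictive pmf is computed against the
    atlas; the sample is covered at q if its true origin's nearest grid
    cell lies in the q-region. Coverage is monotone non-decreasing in q, so
    the smallest q on a fine search grid (coarse ``coarse_step`` sweep
    refined to ``fine_step`` around the solution) with empirical coverage
    >= level is returned per level.
    """
    if calibration.n_samples == 0:
        raise CalibrationError("empty calibration set")
    if list(calibration.taxon_ids) != list(atlas.taxon_ids):
        raise AlignmentError("calibration taxa must match atlas taxa exactly")
    for level in levels:
        if not 0.0 < level < 1.0:
            raise InvalidInputError(f"nominal level {level} outside (0, 1)")

    logP, log1mP = _clipped_log_probs(atlas)
    Yf = calibration.Y.astype(float)
    # (N cells, n samples) log-likelihood fields, all queries at once
    LL = logP @ Yf.T + log1mP @ (1.0 - Yf.T)
    true_cells = atlas.grid.nearest_cells(calibration.lats, calibration.lons)

    n = calibration.n_samples
    min_mass = np.empty(n)
    for i in range(n):
        min_mass[i] = minimal_covering_mass(predictive_pmf(LL[:, i]), int(true_cells[i]))

    def coverage(q: float) -> float:
        return float(np.mean(min_mass < q))

    out: dict[float, ThresholdCalibration] = {}
    for level in levels:
        q_sel = 1.0
        coarse = np.round(np.arange(coarse_step, 1.0 + 1e-9, coarse_step), 10)
        for q in coarse:
            if coverage(q) >= level:
                q_sel = float(q)
                break
        fine = np.round(
            np.arange(q_sel - coarse_step + fine_step, q_sel + 1e-9, fine_step), 10
        )
        for q in fine:
            if q > 0 and coverage(q) >= level:
                q_sel = float(q)
                break
        out[level] = ThresholdCalibration(
            level=float(level), q=q_sel, achieved_coverage=coverage(q_sel)
        )
    return CalibrationResult(levels=out, n_calibration=n)
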