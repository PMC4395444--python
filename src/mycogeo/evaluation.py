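"""Cross-validated assessment of origin prediction.

Protocol: split samples into k folds; for each fold, fit the atlas on 80%
of the training data (subtraining), calibrate region thresholds on the
remaining 20% (subtesting), then predict every test sample with the
subtraining-fit atlas. Prediction error is the great-circle distance (km)
between predicted and true origin; coverage is the fraction of test
samples whose true origin falls inside their calibrated region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SplitError
from .geometry import GeoCoordinate, SpatialGrid, great_circle_distance, pairwise_distances
from .prediction import calibrate_threshold, minimal_covering_mass, predictive_pmf, _clipped_log_probs
from .smoothing import FitConfig, SampleTable, fit_atlas

__all__ = [
    "EvaluationRecord",
    "EvaluationReport",
    "kfold_split",
    "subsplit",
    "evaluate",
    "summarize_records",
    "stratified_summary",
]

DEFAULT_LEVELS = (0.5, 0.75, 0.9)

#: Table-1-style bin edges: neighbors within 100 km.
INTENSITY_RADIUS_KM = 100.0
INTENSITY_EDGES = (6, 25)  # low <= 6 < medium <= 25 < high


@dataclass
class EvaluationRecord:
    sample_id: str
    fold: int
    true_origin: GeoCoordinate
    predicted_origin: GeoCoordinate
    error_km: float
    covered: dict[float, bool] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    records: list[EvaluationRecord]
    summary: dict
    levels: tuple[float, ...]
    seed: int
    config: dict = field(default_factory=dict)
    strata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "fold": [r.fold for r in self.records],
                "true_lat": [r.true_origin.lat for r in self.records],
                "true_lon": [r.true_origin.lon for r in self.records],
                "pred_lat": [r.predicted_origin.lat for r in self.records],
                "pred_lon": [r.predicted_origin.lon for r in self.records],
                "error_km": [r.error_km for r in self.records],
                **{
                    f"covered_{level:g}": [r.covered[level] for r in self.records]
                    for level in self.levels
                },
            }
        )

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "records.csv", index=False, float_format="%.17g")
        payload = {
            "seed": self.seed,
            "levels": list(self.levels),
            "config": self.config,
            "summary": self.summary,
            "strata": self.strata,
        }
        (d / "summary.json").write_text(json.dumps(payload, indent=1))


def kfold_split(
    n_samples: int, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random disjoint, exhaustive folds of near-equal size (seed-deterministic)."""
    if k < 2:
        raise SplitError("need k >= 2 folds")
    if n_samples < k:
        raise SplitError(f"cannot split {n_samples} samples into {k} folds")
    perm = np.random.default_rng(seed).permutation(n_samples)
    folds = np.array_split(perm, k)
    out = []
    for i, test in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        out.append((np.sort(train), np.sort(test)))
    return out


def subsplit(
    train_indices: Sequence[int], fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split training indices into subtraining (floor(fraction*n)) and subtesting."""
    idx = np.asarray(train_indices, dtype=int)
    n = idx.size
    n_sub = int(np.floor(fraction * n))
    if n < 2 or n_sub < 1 or n_sub >= n:
        raise SplitError(f"cannot subsplit {n} training samples at fraction {fraction}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(idx[perm[:n_sub]]), np.sort(idx[perm[n_sub:]])


def summarize_records(
    records: Sequence[EvaluationRecord], levels: Sequence[float]
) -> dict:
    """Median error, 5%/95% error quantiles and coverage per nominal level."""
    errors = np.array([r.error_km for r in records], dtype=float)
    out = {
        "n": int(errors.size),
        "median_error_km": float(np.median(errors)),
        "error_q05_km": float(np.quantile(errors, 0.05)),
        "error_q95_km": float(np.quantile(errors, 0.95)),
        "coverage": {
            f"{level:g}": float(np.mean([r.covered[level] for r in records]))
            for level in levels
        },
    }
    return out


def evaluate(
    samples: SampleTable,
    grid: SpatialGrid,
    config: FitConfig | None = None,
    k: int = 5,
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: int = 0,
    subtrain_fraction: float = 0.8,
) -> EvaluationReport:
    """k-fold cross-validated prediction error and region coverage.

    Per fold: the atlas is fit on the subtraining split, thresholds are
    calibrated on the subtesting split, and each held-out test sample is
    predicted with that same atlas. All randomness derives from ``seed``.
    """
    config = config or FitConfig()
    levels = tuple(levels)
    records: list[EvaluationRecord] = []
    for fold_id, (train, test) in enumerate(kfold_split(samples.n_samples, k, seed)):
        fold_seed = np.random.SeedSequence([seed, fold_id]).generate_state(1)[0]
        subtrain, subtest = subsplit(train, subtrain_fraction, int(fold_seed))
        atlas = fit_atlas(samples.subset(subtrain), grid, config)
        calib = calibrate_threshold(atlas, samples.subset(subtest), levels)
        thresholds = calib.thresholds()

        test_table = samples.subset(test)
        logP, log1mP = _clipped_log_probs(atlas)
        Yf = test_table.Y.astype(float)
        LL = logP @ Yf.T + log1mP @ (1.0 - Yf.T)  # (N, n_test)
        true_cells = grid.nearest_cells(test_table.lats, test_table.lons)
        for i in range(test_table.n_samples):
            argmax_cell = int(np.argmax(LL[:, i]))
            pred = grid.coordinate(argmax_cell)
            truth = GeoCoordinate(float(test_table.lats[i]), float(test_table.lons[i]))
            mass = minimal_covering_mass(predictive_pmf(LL[:, i]), int(true_cells[i]))
            records.append(
                EvaluationRecord(
                    sample_id=test_table.sample_ids[i],
                    fold=fold_id,
                    true_origin=truth,
                    predicted_origin=pred,
                    error_km=great_circle_distance(truth, pred),
                    covered={lvl: bool(thresholds[lvl] > mass) for lvl in levels},
                )
            )
    return EvaluationReport(
        records=records,
        summary=summarize_records(records, levels),
        levels=levels,
        seed=seed,
        config={"k": k, "subtrain_fraction": subtrain_fraction, **config.to_dict()},
    )


def pooled_coverage_experiment(
    master_seed: int = 1,
    n_seeds: int = 10,
    m: int = 300,
    endemic_fraction: float = 0.7,
    n: int = 400,
    k: int = 5,
    grid_nx: int = 40,
    grid_ny: int = 40,
    levels: Sequence[float] = DEFAULT_LEVELS,
    config: FitConfig | None = None,
) -> dict:
    """Empirical coverage of calibrated regions, pooled over replicates.

    Each replicate draws a fresh synthetic biogeography and sample set,
    runs k-fold cross-validation with per-fold subtrain/subtest threshold
    calibration, and pools the per-sample covered flags across folds and
    replicates. On a well-specified world the pooled coverage at each
    nominal level should match that level up to Monte-Carlo error — the
    central calibration property of the method.
    """
    from .synthetic import DEFAULT_DOMAIN, make_world, simulate_samples

    grid = None
    levels = tuple(levels)
    flags: dict[float, list[bool]] = {lvl: [] for lvl in levels}
    errors: list[float] = []
    for rep in range(n_seeds):
        ws, ss, es = (
            int(x) % (2**31)
            for x in np.random.SeedSequence([master_seed, rep]).generate_state(3)
        )
        world = make_world(m, endemic_fraction, seed=ws)
        samples = simulate_samples(world, n, seed=ss)
        if grid is None:
            from .geometry import build_grid

            grid = build_grid(world.domain, grid_nx, grid_ny)
        report = evaluate(samples, grid, config, k=k, levels=levels, seed=es)
        for r in report.records:
            errors.append(r.error_km)
            for lvl in levels:
                flags[lvl].append(r.covered[lvl])
    return {
        "coverage": {lvl: float(np.mean(flags[lvl])) for lvl in levels},
        "n_records": len(errors),
        "median_error_km": float(np.median(errors)),
    }


# ---------------------------------------------------------------------------
# stratified summaries


def _sampling_intensity_strata(samples: SampleTable) -> dict[str, str]:
    """Count of *other* samples within 100 km, binned as in the field's
    low/medium/high sampling-intensity convention."""
    D = pairwise_distances(samples.lats, samples.lons, samples.lats, samples.lons)
    counts = (D <= INTENSITY_RADIUS_KM).sum(axis=1) - 1
    lo, hi = INTENSITY_EDGES
    labels = np.where(counts <= lo, "low", np.where(counts <= hi, "medium", "high"))
    return dict(zip(samples.sample_ids, labels))


def _richness_strata(samples: SampleTable) -> dict[str, str]:
    """Per-sample taxon count binned by tertiles (low <= t1 < medium <= t2 < high)."""
    rich = samples.richness().astype(float)
    t1, t2 = np.quantile(rich, [1 / 3, 2 / 3])
    labels = np.where(rich <= t1, "low", np.where(rich <= t2, "medium", "high"))
    return dict(zip(samples.sample_ids, labels))


def stratified_summary(
    report: EvaluationReport,
    labels: Mapping[str, str] | None = None,
    samples: SampleTable | None = None,
) -> dict[str, dict[str, dict]]:
    """Per-stratum summaries, keyed by covariate then stratum.

    ``labels`` supplies an arbitrary user covariate (sample_id -> stratum;
    samples missing from it fall into "unlabeled"). When ``samples`` is
    given, computed "sampling_intensity" and "richness" strata are added.
    """
    covariates: dict[str, Mapping[str, str]] = {}
    if labels is not None:
        covariates["custom"] = labels
    if samples is not None:
        covariates["sampling_intensity"] = _sampling_intensity_strata(samples)
        covariates["richness"] = _richness_strata(samples)

    out: dict[str, dict[str, dict]] = {}
    for name, mapping in covariates.items():
        groups: dict[str, list[EvaluationRecord]] = {}
        for r in report.records:
            groups.setdefault(mapping.get(r.sample_id, "unlabeled"), []).append(r)
        out[name] = {
            stratum: summarize_records(recs, report.levels)
            for stratum, recs in sorted(groups.items())
        }
    return out
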