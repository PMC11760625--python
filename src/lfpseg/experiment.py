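"""Parameter-search protocol: grid sweep, split, best-10 averaging,
low-SNR fine-tuning and per-slice reporting.

The optimization matrix sweeps each algorithm's tunables (threshold in
sigma units, the delta integration window, and — for the z-score detector —
the memory lag).  Every grid cell is evaluated on every training record by
the MCDA score; the parameter vectors of the ten best cells are averaged
and snapped back to the grid to form the winning combination.  Records with
SNR below 20 dB get a further +/-1-grid-step neighborhood search.  The
report stage emits per-record and per-slice metric tables plus the Pearson
correlation between per-record score and SNR.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ampde import AMPDEParams, ampde_segment
from .core import AnnotationTrack, DataError, LFPRecord
from .density import DensityParams
from .metrics import MCDAWeights, MatchCriteria, evaluate
from .synthetic import measure_snr
from .zdensity import ZdensityParams, zdensity_segment

logger = logging.getLogger("lfpseg")

__all__ = [
    "GridSpec",
    "TrialResult",
    "split_dataset",
    "run_algorithm",
    "run_grid",
    "fine_tune_low_snr",
    "report",
]

LOW_SNR_DB = 20.0

REPORT_COLUMNS = [
    "precision_ictal",
    "precision_interictal",
    "recall_ictal",
    "recall_interictal",
    "jaccard_ictal",
    "jaccard_interictal",
    "f_score_ictal",
    "f_score_interictal",
    "score",
]


@dataclass
class GridSpec:
    """Cartesian parameter grid; values per parameter name."""

    params: dict[str, list] = field(default_factory=dict)

    @classmethod
    def zdensity_default(cls) -> "GridSpec":
        return cls(
            params={
                "threshold_sigma": [4.0, 5.0, 6.0],
                "delta_s": [3.0, 4.0, 5.0],
                "lag_s": [0.125, 0.25, 0.5],
            }
        )

    @classmethod
    def ampde_default(cls) -> "GridSpec":
        return cls(
            params={
                "threshold_sigma": [3.0, 4.0, 5.0, 6.0],
                "delta_s": [1.5, 2.0, 2.5],
            }
        )

    def cells(self) -> list[dict]:
        names = list(self.params)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.params[n] for n in names))
        ]

    def snap(self, name: str, value: float) -> float:
        """Nearest grid value; ties break toward the lower value."""
        values = sorted(self.params[name])
        return min(values, key=lambda v: (abs(v - value), v))


@dataclass
class TrialResult:
    params: dict
    scores: list[float]
    snr_db: list[float]

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores)) if self.scores else 0.0


def split_dataset(records: list, fraction: float = 0.7, seed: int = 0):
    """Seeded record-level partition into (train, validation)."""
    if not 0 < fraction < 1:
        raise DataError("fraction must lie in (0, 1)")
    if len(records) < 2:
        raise DataError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(fraction * len(records)))
    n_train = min(max(n_train, 1), len(records) - 1)
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train:]]
    return train, val


def run_algorithm(
    algorithm: str,
    record: LFPRecord,
    overrides: dict | None = None,
    density_params: DensityParams | None = None,
) -> AnnotationTrack:
    """Run one detector with default parameters overridden by a grid cell."""
    overrides = dict(overrides or {})
    if algorithm == "zdensity":
        params = replace(ZdensityParams(), **overrides)
        _, _, track = zdensity_segment(record, params, density_params)
    elif algorithm == "ampde":
        params = replace(AMPDEParams(), **overrides)
        _, _, track = ampde_segment(record, params, density_params)
    else:
        raise DataError(f"unknown algorithm {algorithm!r}")
    return track


def _evaluate_cell(
    algorithm: str,
    dataset: list[tuple[LFPRecord, AnnotationTrack]],
    cell: dict,
    density_params: DensityParams | None,
    criteria: MatchCriteria,
    weights: MCDAWeights,
) -> TrialResult:
    scores, snrs = [], []
    for record, ref in dataset:
        out = run_algorithm(algorithm, record, cell, density_params)
        rep = evaluate(ref, out, criteria, weights)
        scores.append(rep.score)
        try:
            snrs.append(measure_snr(record, ref))
        except DataError:
            snrs.append(float("nan"))
    return TrialResult(params=cell, scores=scores, snr_db=snrs)


def run_grid(
    dataset: list[tuple[LFPRecord, AnnotationTrack]],
    grid: GridSpec,
    algorithm: str,
    density_params: DensityParams | None = None,
    criteria: MatchCriteria = MatchCriteria(),
    weights: MCDAWeights = MCDAWeights(),
    top_n: int = 10,
) -> tuple[dict, list[TrialResult]]:
    """Exhaustive sweep; returns (winning params, full ranked results).

    The winning combination averages each parameter over the ``top_n``
    best-scoring cells and snaps the mean to the nearest grid value.  Grids
    smaller than ``top_n`` are averaged whole (with a warning).
    """
    cells = grid.cells()
    if not cells or not dataset:
        raise DataError("empty grid or dataset")
    results = [
        _evaluate_cell(algorithm, dataset, cell, density_params, criteria, weights)
        for cell in cells
    ]
    ranked = sorted(
        range(len(results)), key=lambda i: (-results[i].mean_score, i)
    )
    results = [results[i] for i in ranked]
    if len(results) < top_n:
        logger.warning(
            "grid has %d cells < top_n=%d; averaging all", len(results), top_n
        )
    top = results[: min(top_n, len(results))]
    winning = {
        name: grid.snap(name, float(np.mean([t.params[name] for t in top])))
        for name in grid.params
    }
    logger.info("grid winner (%s): %s", algorithm, winning)
    return winning, results


def fine_tune_low_snr(
    dataset_low: list[tuple[LFPRecord, AnnotationTrack]],
    winning: dict,
    grid: GridSpec,
    algorithm: str,
    density_params: DensityParams | None = None,
    criteria: MatchCriteria = MatchCriteria(),
    weights: MCDAWeights = MCDAWeights(),
) -> dict:
    """+/-1-grid-step neighborhood search restricted to low-SNR records.

    Returns the winning parameters unchanged when the subset is empty; the
    adjustment never leaves the declared neighborhood.
    """
    if not dataset_low:
        return dict(winning)
    neighborhood: dict[str, list] = {}
    for name, values in grid.params.items():
        values = sorted(values)
        idx = values.index(grid.snap(name, winning[name]))
        neighborhood[name] = values[max(0, idx - 1) : idx + 2]
    local = GridSpec(params=neighborhood)
    incumbent = {n: grid.snap(n, winning[n]) for n in grid.params}
    best_cell = dict(incumbent)
    best_score = _evaluate_cell(
        algorithm, dataset_low, incumbent, density_params, criteria, weights
    ).mean_score
    for cell in local.cells():
        if cell == incumbent:
            continue
        res = _evaluate_cell(
            algorithm, dataset_low, cell, density_params, criteria, weights
        )
        # ties keep the incumbent: only strict improvement moves the params
        if res.mean_score > best_score + 1e-12:
            best_cell, best_score = cell, res.mean_score
    return best_cell


def report(
    dataset_val: list[tuple[LFPRecord, AnnotationTrack]],
    params: dict,
    algorithm: str,
    density_params: DensityParams | None = None,
    criteria: MatchCriteria = MatchCriteria(),
    weights: MCDAWeights = MCDAWeights(),
) -> dict:
    """Per-record table, per-slice aggregation and score-vs-SNR correlation.

    Slice identity is read from ``channel_meta['slice']`` (falling back to
    the record id).  The Pearson correlation is reported as ``None`` when
    undefined (fewer than two records or zero variance).
    """
    if not dataset_val:
        raise DataError("validation set is empty")
    rows = []
    for record, ref in dataset_val:
        out = run_algorithm(algorithm, record, params, density_params)
        rep = evaluate(ref, out, criteria, weights)
        try:
            snr = measure_snr(record, ref)
        except DataError:
            snr = float("nan")
        rows.append(
            {
                "record_id": record.record_id,
                "slice": record.channel_meta.get("slice", record.record_id),
                "precision_ictal": rep.ictal.precision,
                "precision_interictal": rep.interictal.precision,
                "recall_ictal": rep.ictal.recall,
                "recall_interictal": rep.interictal.recall,
                "jaccard_ictal": rep.ictal.jaccard,
                "jaccard_interictal": rep.interictal.jaccard,
                "f_score_ictal": rep.ictal.f_score,
                "f_score_interictal": rep.interictal.f_score,
                "score": rep.score,
                "snr_db": snr,
            }
        )
    per_record = pd.DataFrame(rows)
    per_slice = (
        per_record.groupby("slice")[REPORT_COLUMNS + ["snr_db"]].mean().reset_index()
    )
    score = per_record["score"].to_numpy(dtype=float)
    snr = per_record["snr_db"].to_numpy(dtype=float)
    ok = np.isfinite(score) & np.isfinite(snr)
    if ok.sum() >= 2 and np.std(score[ok]) > 0 and np.std(snr[ok]) > 0:
        from scipy.stats import pearsonr

        corr = float(pearsonr(score[ok], snr[ok]).statistic)
    else:
        corr = None
    return {
        "per_record": per_record,
        "per_slice": per_slice,
        "score_snr_pearson_r": corr,
    }
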