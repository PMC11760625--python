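"""Event-matching evaluation metrics and the weighted MCDA score.

Detections are compared with reference annotations per class (ictal,
interictal) by greedy one-to-one interval matching: an output event is a
true positive for a same-class reference event when it covers more than
``min_coincidence`` of the reference (coincidence ratio = intersection
length / reference length) and its own length does not exceed
``max_length_ratio`` times the reference length.  Unmatched outputs are
false positives, unmatched references false negatives.

Per class the report carries precision, recall, F-score (0/0 -> 0
convention) and the Jaccard index of the labeled time sets.  The scalar
multi-criteria (MCDA) score is the fixed weighted combination

    score = 0.60 P_ictal + 0.20 J_ictal + 0.10 R_ictal
          + 0.05 P_interictal + 0.05 R_interictal

which prioritizes precise ictal detection; the weights are configurable
for retraining toward other objectives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import AnnotationTrack, EventInterval, ICTAL, INTERICTAL, ParameterError

__all__ = [
    "MatchCriteria",
    "ConfusionCounts",
    "MCDAWeights",
    "ClassMetrics",
    "MetricsReport",
    "coincidence_ratio",
    "match_events",
    "compute_metrics",
    "mcda_score",
    "evaluate",
]

EVENT_CLASSES = (ICTAL, INTERICTAL)


@dataclass(frozen=True)
class MatchCriteria:
    min_coincidence: float = 0.8
    max_length_ratio: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.min_coincidence <= 1:
            raise ParameterError("min_coincidence must lie in (0, 1]")
        if self.max_length_ratio < 1:
            raise ParameterError("max_length_ratio must be >= 1")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass(frozen=True)
class MCDAWeights:
    precision_ictal: float = 0.60
    jaccard_ictal: float = 0.20
    recall_ictal: float = 0.10
    precision_interictal: float = 0.05
    recall_interictal: float = 0.05

    def total(self) -> float:
        return (
            self.precision_ictal
            + self.jaccard_ictal
            + self.recall_ictal
            + self.precision_interictal
            + self.recall_interictal
        )


@dataclass
class ClassMetrics:
    precision: float = 0.0
    recall: float = 0.0
    f_score: float = 0.0
    jaccard: float = 0.0


@dataclass
class MetricsReport:
    ictal: ClassMetrics = field(default_factory=ClassMetrics)
    interictal: ClassMetrics = field(default_factory=ClassMetrics)
    score: float | None = None

    def to_dict(self) -> dict:
        d = {
            "ictal": vars(self.ictal).copy(),
            "interictal": vars(self.interictal).copy(),
        }
        if self.score is not None:
            d["score"] = self.score
        return d


def coincidence_ratio(ref: EventInterval, out: EventInterval) -> float:
    """Intersection length over reference length, 0 when disjoint."""
    ref_len = ref.end_s - ref.start_s
    if ref_len <= 0:
        raise ParameterError("zero-length reference interval")
    inter = min(ref.end_s, out.end_s) - max(ref.start_s, out.start_s)
    return max(0.0, inter) / ref_len


def match_events(
    reference: AnnotationTrack,
    output: AnnotationTrack,
    criteria: MatchCriteria = MatchCriteria(),
) -> dict[int, ConfusionCounts]:
    """Greedy one-to-one temporal matching per class.

    Each output event claims the first unmatched same-class reference that
    satisfies both criteria; each reference is matched at most once.
    """
    counts: dict[int, ConfusionCounts] = {}
    for cls in EVENT_CLASSES:
        refs = reference.of_label(cls)
        outs = output.of_label(cls)
        c = ConfusionCounts()
        claimed: set[int] = set()
        for o in outs:
            o_len = o.end_s - o.start_s
            for ri, r in enumerate(refs):
                if ri in claimed:
                    continue
                if (
                    coincidence_ratio(r, o) > criteria.min_coincidence
                    and o_len <= criteria.max_length_ratio * (r.end_s - r.start_s)
                ):
                    c.tp += 1
                    claimed.add(ri)
                    break
            else:
                c.fp += 1
        c.fn = len(refs) - len(claimed)
        counts[cls] = c
    return counts


def _merged(intervals: list[EventInterval]) -> list[tuple[float, float]]:
    spans = sorted((iv.start_s, iv.end_s) for iv in intervals)
    out: list[tuple[float, float]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _jaccard_time(a: list[EventInterval], b: list[EventInterval]) -> float:
    """Jaccard index of two interval sets by time measure.

    Exact continuous-time form of the per-sample label-set Jaccard.
    An empty union yields 0 by the same convention as the count metrics.
    """
    ma, mb = _merged(a), _merged(b)
    len_a = sum(e - s for s, e in ma)
    len_b = sum(e - s for s, e in mb)
    inter = 0.0
    i = j = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if e > s:
            inter += e - s
        if ma[i][1] <= mb[j][1]:
            i += 1
        else:
            j += 1
    union = len_a + len_b - inter
    return inter / union if union > 0 else 0.0


def _prf(c: ConfusionCounts) -> tuple[float, float, float]:
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def compute_metrics(
    counts: dict[int, ConfusionCounts],
    reference: AnnotationTrack,
    output: AnnotationTrack,
) -> MetricsReport:
    """Per-class precision/recall/F from counts, Jaccard from time overlap."""
    report = MetricsReport()
    for cls, slot in ((ICTAL, report.ictal), (INTERICTAL, report.interictal)):
        p, r, f = _prf(counts[cls])
        slot.precision, slot.recall, slot.f_score = p, r, f
        slot.jaccard = _jaccard_time(output.of_label(cls), reference.of_label(cls))
    return report


def mcda_score(
    report: MetricsReport, weights: MCDAWeights = MCDAWeights()
) -> float:
    """Weighted multi-criteria score in [0, 1]."""
    if abs(weights.total() - 1.0) > 1e-9:
        raise ParameterError(f"MCDA weights sum to {weights.total()}, not 1")
    return (
        weights.precision_ictal * report.ictal.precision
        + weights.jaccard_ictal * report.ictal.jaccard
        + weights.recall_ictal * report.ictal.recall
        + weights.precision_interictal * report.interictal.precision
        + weights.recall_interictal * report.interictal.recall
    )


def evaluate(
    reference: AnnotationTrack,
    output: AnnotationTrack,
    criteria: MatchCriteria = MatchCriteria(),
    weights: MCDAWeights = MCDAWeights(),
) -> MetricsReport:
    """Convenience: match, compute metrics, attach the MCDA score."""
    counts = match_events(reference, output, criteria)
    report = compute_metrics(counts, reference, output)
    report.score = mcda_score(report, weights)
    return report
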