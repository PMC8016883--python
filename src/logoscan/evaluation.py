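"""Detection scoring against ground truth (point rate, segment rate,
G-score) and size-matched permutation tests for annotation enrichment.

Intervals are half-open ``(start, end)`` pairs over either SNP indices
(simulations) or base pairs (real tracks); the same arithmetic applies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class PowerReport:
    point_rate: float
    segment_rate: float
    g_score: float
    n_truth: int
    n_detected: int

    def as_dict(self) -> dict:
        return {
            "point_rate": self.point_rate,
            "segment_rate": self.segment_rate,
            "g_score": self.g_score,
            "n_truth": self.n_truth,
            "n_detected": self.n_detected,
        }


@dataclass
class AnnotationTrack:
    """Non-overlapping genomic intervals, per chromosome."""

    intervals: dict  # chrom -> list[(start, end)]
    label: str = ""

    def __post_init__(self):
        self.intervals = {c: merge_intervals(iv) for c, iv in self.intervals.items()}

    @classmethod
    def from_bed(cls, path, label: str = "") -> "AnnotationTrack":
        out: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                try:
                    iv = (int(parts[1]), int(parts[2]))
                except ValueError:
                    continue  # tolerate a header line (e.g. regions TSV)
                out.setdefault(parts[0], []).append(iv)
        return cls(intervals=out, label=label or str(path))

    def total_bp(self) -> int:
        return sum(e - s for iv in self.intervals.values() for s, e in iv)


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_overlap(a, b) -> int:
    """Total overlap between two merged interval lists."""
    a, b = merge_intervals(a), merge_intervals(b)
    i = j = tot = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            tot += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return tot


def subtract_intervals(target, conditioning) -> list[tuple[int, int]]:
    """target \\ conditioning at bp / index level."""
    target = merge_intervals(target)
    conditioning = merge_intervals(conditioning)
    out = []
    for s, e in target:
        cur = s
        for cs, ce in conditioning:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _validate(truth, detected):
    truth = merge_intervals(truth)
    if not truth:
        raise EvaluationError("truth interval set is empty")
    return truth, merge_intervals(detected)


# ---------------------------------------------------------------------------
# power metrics
# ---------------------------------------------------------------------------

def point_detection_rate(truth, detected) -> float:
    """|union(truth) intersect union(detected)| / |union(truth)|."""
    truth, detected = _validate(truth, detected)
    total = sum(e - s for s, e in truth)
    return interval_overlap(truth, detected) / total


def segment_detection_rate(truth, detected) -> float:
    """Fraction of truth segments overlapped by at least one detection."""
    truth, detected = _validate(truth, detected)
    hit = sum(1 for t in truth if interval_overlap([t], detected) > 0)
    return hit / len(truth)


def g_score(truth, detected) -> float:
    """Mean over truth segments j of max_k |Rhat_k ^ R_j| / sqrt(|Rhat_k| |R_j|).

    Jointly rewards sensitivity and boundary precision; 0 when nothing is
    detected, 1 iff every truth segment is matched exactly.
    """
    truth, detected = _validate(truth, detected)
    if not detected:
        return 0.0
    scores = []
    for ts, te in truth:
        best = 0.0
        for ds, de in detected:
            ov = max(0, min(te, de) - max(ts, ds))
            if ov:
                best = max(best, ov / np.sqrt((de - ds) * (te - ts)))
        scores.append(best)
    return float(np.mean(scores))


def power_report(truth, detected) -> PowerReport:
    truth_m, detected_m = _validate(truth, detected)
    return PowerReport(
        point_rate=point_detection_rate(truth_m, detected_m),
        segment_rate=segment_detection_rate(truth_m, detected_m),
        g_score=g_score(truth_m, detected_m),
        n_truth=len(truth_m),
        n_detected=len(detected_m),
    )


# ---------------------------------------------------------------------------
# enrichment permutation test
# ---------------------------------------------------------------------------

def _place_segments(sizes, genome: dict, rng, max_tries: int = 1000):
    """Place size-matched, non-overlapping segments uniformly at random;
    chromosome chosen proportional to its length."""
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    prob = lengths / lengths.sum()
    placed: dict = {c: [] for c in chroms}
    for size in sorted(sizes, reverse=True):
        for _ in range(max_tries):
            c = chroms[rng.choice(len(chroms), p=prob)]
            if genome[c] < size:
                continue
            s = int(rng.integers(0, genome[c] - size + 1))
            cand = (s, s + size)
            if not any(max(cand[0], s2) < min(cand[1], e2) for s2, e2 in placed[c]):
                placed[c].append(cand)
                break
        else:
            raise EvaluationError(
                "could not place permutation segments without overlap; use a larger genome"
            )
    return placed


def enrichment_permutation(
    detected: AnnotationTrack,
    annotation: AnnotationTrack,
    genome: dict,
    n_perm: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Size-matched permutation test of detected-segment overlap with an
    annotation track.

    Returns (fold, p) where fold = observed overlap / mean permuted overlap
    and p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    sizes = [e - s for iv in detected.intervals.values() for s, e in iv]
    if not sizes:
        raise EvaluationError("detected track is empty")
    observed = sum(
        interval_overlap(detected.intervals.get(c, []), annotation.intervals.get(c, []))
        for c in set(detected.intervals) | set(annotation.intervals)
    )
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        placed = _place_segments(sizes, genome, rng)
        perm[i] = sum(
            interval_overlap(placed.get(c, []), annotation.intervals.get(c, []))
            for c in placed
        )
    mean_perm = perm.mean()
    fold = observed / mean_perm if mean_perm > 0 else (0.0 if observed == 0 else np.inf)
    p = (1.0 + float((perm >= observed).sum())) / (1.0 + n_perm)
    if observed == 0 and mean_perm == 0:
        fold = 0.0
    return float(fold), float(p)


def conditional_annotation(target: AnnotationTrack, conditioning: AnnotationTrack) -> AnnotationTrack:
    """bp-level interval subtraction: target minus the conditioning track."""
    out = {
        c: subtract_intervals(iv, conditioning.intervals.get(c, []))
        for c, iv in target.intervals.items()
    }
    return AnnotationTrack(
        intervals={c: iv for c, iv in out.items() if iv},
        label=f"{target.label} \\ {conditioning.label}",
    )
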