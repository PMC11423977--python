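"""CGM preprocessing: grid alignment, gap handling, normalization, windowing.

The pipeline converts an irregular sensor trace into supervised windows in
four steps:

1. align every sample to a strict 5-minute grid (nearest slot, ties toward
   the earlier slot), marking unfilled slots missing;
2. fill missing runs of up to an hour by linear interpolation between the
   flanking observations, and split the series wherever a run exceeds an
   hour so no values are fabricated across long sensor dropouts;
3. z-score with mean and standard deviation pooled over the cohort's
   *training* data only (population convention), applied unchanged to
   validation and test data;
4. slide a history window of L steps over each contiguous segment and pair
   it with the value p steps ahead; windows never span a segment boundary.

Patients are partitioned between training and test (no patient appears in
both); the validation set is the chronological tail of each training
patient's data, so validation never sees the future of the data it tunes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GlucoseTrace

GRID_MIN = 5

__all__ = [
    "GriddedSeries", "Segment", "NormalizationParams", "WindowSet", "SplitPlan",
    "align_to_grid", "impute_and_segment",
    "fit_normalizer", "apply_normalizer", "invert_normalizer",
    "split_cohort", "partition_segments", "make_windows", "build_datasets",
]


@dataclass
class GriddedSeries:
    patient_id: str
    start_time: int                 # minutes
    values: np.ndarray              # nan marks a missing slot

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class Segment:
    """A contiguous 5-minute-grid glucose series with no missing entries."""

    patient_id: str
    start_time: int
    values: np.ndarray
    imputed_mask: np.ndarray

    def __post_init__(self):
        if len(self.values) < 1:
            raise ValueError("empty segment")
        if np.isnan(self.values).any():
            raise ValueError("segment contains missing values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NormalizationParams:
    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive (constant training data?)")


@dataclass
class WindowSet:
    """Supervised (history, target) pairs for one prediction horizon."""

    inputs: np.ndarray              # (n_windows, L) normalized values
    targets: np.ndarray             # (n_windows,) normalized values
    L: int
    horizon_steps: int
    patient_ids: list[str] = field(default_factory=list)
    starts: np.ndarray | None = None    # window start index within its segment

    @property
    def n_windows(self) -> int:
        return len(self.targets)


@dataclass
class SplitPlan:
    train_patients: list[str]
    test_patients: list[str]
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    per_patient: bool = False       # predefined per-patient train/test partitions

    def __post_init__(self):
        if not self.per_patient and set(self.train_patients) & set(self.test_patients):
            raise ValueError("train and test patients must be disjoint")


def align_to_grid(trace: GlucoseTrace) -> GriddedSeries:
    """Map samples to the 5-minute grid spanning first to last timestamp."""
    times = np.asarray(trace.times, dtype=float)
    if len(times) == 0:
        raise ValueError("empty trace")
    if len(np.unique(times)) != len(times):
        raise ValueError(f"duplicate timestamps for patient {trace.patient_id}")
    t0 = times[0]
    offsets = times - t0
    slots = np.floor_divide(offsets, GRID_MIN).astype(int)
    rem = offsets - GRID_MIN * slots
    slots = slots + (rem > GRID_MIN / 2)        # tie (rem == 2.5) stays earlier
    n_slots = slots[-1] + 1
    values = np.full(n_slots, np.nan)
    dist = np.full(n_slots, np.inf)
    for s, t, v in zip(slots, offsets, trace.values):
        d = abs(t - s * GRID_MIN)
        if d < dist[s]:                          # tie keeps the earlier sample
            values[s] = v
            dist[s] = d
    return GriddedSeries(patient_id=trace.patient_id,
                         start_time=int(t0), values=values)


def impute_and_segment(gridded: GriddedSeries, max_gap_min: int = 60) -> list[Segment]:
    """Interpolate short gaps, split at gaps longer than ``max_gap_min``.

    A missing run of exactly ``max_gap_min`` is still interpolated; only
    strictly longer runs split the series.  Leading and trailing missing
    slots are dropped (they have no flanking value to interpolate from).
    """
    max_gap_slots = max_gap_min // GRID_MIN
    values = gridded.values
    missing = np.isnan(values)
    if missing.all():
        return []
    first = int(np.argmax(~missing))
    last = len(values) - int(np.argmax(~missing[::-1]))
    segments: list[Segment] = []
    seg_start = first
    i = first
    while i < last:
        if not missing[i]:
            i += 1
            continue
        run_start = i
        while i < last and missing[i]:
            i += 1
        run_len = i - run_start
        if run_len > max_gap_slots:
            segments.append(_cut(gridded, seg_start, run_start))
            seg_start = i
    segments.append(_cut(gridded, seg_start, last))
    return segments


def _cut(gridded: GriddedSeries, lo: int, hi: int) -> Segment:
    vals = gridded.values[lo:hi].copy()
    mask = np.isnan(vals)
    if mask.any():
        idx = np.arange(len(vals))
        vals[mask] = np.interp(idx[mask], idx[~mask], vals[~mask])
    return Segment(patient_id=gridded.patient_id,
                   start_time=gridded.start_time + GRID_MIN * lo,
                   values=vals, imputed_mask=mask)


def fit_normalizer(training_segments: list[Segment]) -> NormalizationParams:
    """Pooled mean/SD over all training segments (population convention)."""
    pooled = np.concatenate([s.values for s in training_segments])
    return NormalizationParams(mu=float(pooled.mean()),
                               sigma=float(pooled.std(ddof=0)))


def apply_normalizer(params: NormalizationParams, values: np.ndarray) -> np.ndarray:
    return (np.asarray(values, dtype=float) - params.mu) / params.sigma


def invert_normalizer(params: NormalizationParams, z: np.ndarray) -> np.ndarray:
    return np.asarray(z, dtype=float) * params.sigma + params.mu


def split_cohort(traces: list[GlucoseTrace], test_fraction: float = 0.2,
                 val_fraction: float = 0.2, ohio_mode: bool = False,
                 seed: int = 0) -> SplitPlan:
    """Assign patients to train/test pools.

    Cohort mode partitions patients 80/20 so no test patient contributes any
    training data; ``ohio_mode`` keeps every patient in both sides with a
    chronological within-patient train/test cut, mirroring datasets that ship
    predefined per-patient partitions.  Validation is always the
    chronological tail of the training span.
    """
    ids = [t.patient_id for t in traces]
    if ohio_mode:
        return SplitPlan(train_patients=ids, test_patients=ids,
                         val_fraction=val_fraction, test_fraction=test_fraction,
                         per_patient=True)
    if len(ids) < 2:
        raise ValueError("cohort mode requires at least 2 patients")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = max(1, int(round(test_fraction * len(ids))))
    return SplitPlan(train_patients=sorted(order[n_test:]),
                     test_patients=sorted(order[:n_test]),
                     val_fraction=val_fraction, test_fraction=test_fraction)


def _chronological_cut(segments: list[Segment], tail_fraction: float
                       ) -> tuple[list[Segment], list[Segment]]:
    """Split a patient's chronologically ordered segments at a slot-count cut."""
    segments = sorted(segments, key=lambda s: s.start_time)
    total = sum(len(s) for s in segments)
    cut = total - int(round(tail_fraction * total))
    head: list[Segment] = []
    tail: list[Segment] = []
    seen = 0
    for seg in segments:
        if seen + len(seg) <= cut:
            head.append(seg)
        elif seen >= cut:
            tail.append(seg)
        else:
            k = cut - seen
            if k > 0:
                head.append(Segment(seg.patient_id, seg.start_time,
                                    seg.values[:k], seg.imputed_mask[:k]))
            tail.append(Segment(seg.patient_id,
                                seg.start_time + GRID_MIN * k,
                                seg.values[k:], seg.imputed_mask[k:]))
        seen += len(seg)
    return head, tail


def partition_segments(plan: SplitPlan, segments_by_patient: dict[str, list[Segment]]
                       ) -> dict[str, list[Segment]]:
    """Materialize a :class:`SplitPlan` into train/val/test segment lists."""
    out: dict[str, list[Segment]] = {"train": [], "val": [], "test": []}
    for pid, segs in segments_by_patient.items():
        if plan.per_patient:
            span, test = _chronological_cut(segs, plan.test_fraction)
            train, val = _chronological_cut(span, plan.val_fraction)
            out["train"] += train
            out["val"] += val
            out["test"] += test
        elif pid in plan.test_patients:
            out["test"] += segs
        elif pid in plan.train_patients:
            train, val = _chronological_cut(segs, plan.val_fraction)
            out["train"] += train
            out["val"] += val
    return out


def make_windows(segments: list[Segment], L: int = 24,
                 horizons: list[int] = (6, 12),
                 params: NormalizationParams | None = None
                 ) -> dict[int, WindowSet]:
    """Build per-horizon sliding-window datasets from contiguous segments.

    Each segment of length N contributes max(0, N - L - p + 1) windows for
    horizon p: input steps t-L+1..t, target step t+p, all in normalized units
    when ``params`` is given.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    horizons = list(horizons)
    if any(p <= 0 for p in horizons):
        raise ValueError("horizons must be positive")
    out: dict[int, WindowSet] = {}
    for p in horizons:
        inputs, targets, pids, starts = [], [], [], []
        for seg in segments:
            vals = seg.values
            if params is not None:
                vals = apply_normalizer(params, vals)
            n = len(vals) - L - p + 1
            if n <= 0:
                continue
            idx = np.arange(n)[:, None] + np.arange(L)[None, :]
            inputs.append(vals[idx])
            targets.append(vals[np.arange(n) + L + p - 1])
            pids += [seg.patient_id] * n
            starts.append(np.arange(n))
        if inputs:
            out[p] = WindowSet(np.concatenate(inputs), np.concatenate(targets),
                               L, p, pids, np.concatenate(starts))
        else:
            out[p] = WindowSet(np.zeros((0, L)), np.zeros(0), L, p, [],
                               np.zeros(0, dtype=int))
    return out


def build_datasets(traces: list[GlucoseTrace], L: int = 24,
                   horizons: list[int] = (6, 12), seed: int = 0,
                   ohio_mode: bool = False, max_gap_min: int = 60) -> dict:
    """Full preprocessing for one cohort: grid, segment, split, normalize, window.

    Returns a dict with the split plan, normalization parameters fitted on the
    training split only, per-split per-horizon window sets, and patient sex
    labels for demographic slicing.
    """
    segments_by_patient = {
        t.patient_id: impute_and_segment(align_to_grid(t), max_gap_min)
        for t in traces
    }
    plan = split_cohort(traces, ohio_mode=ohio_mode, seed=seed)
    parts = partition_segments(plan, segments_by_patient)
    params = fit_normalizer(parts["train"])
    windows = {split: make_windows(segs, L, horizons, params)
               for split, segs in parts.items()}
    return {
        "plan": plan,
        "params": params,
        "segments": parts,
        "windows": windows,
        "sex_by_patient": {t.patient_id: t.sex for t in traces},
    }
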