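"""Analytical and clinical evaluation of glucose forecasts.

Analytical metrics on a prediction set of N (reference G_i, prediction Ghat_i)
pairs in mg/dL:

    RMSE = sqrt( sum (G - Ghat)^2 / N )
    COD  = 1 - sum (G - Ghat)^2 / sum (G - Gbar)^2        (R^2)
    MAD  = sum |G - Ghat| / N
    FIT  = (1 - RMSE / sqrt( sum (G - Gbar)^2 / N )) * 100
    MADP = mean( |G - Ghat| / G ) * 100

FIT measures improvement over the mean-prediction baseline, so FIT and COD
satisfy FIT = (1 - sqrt(1 - COD)) * 100 whenever both are defined.

Clinical scoring uses the Clarke Error Grid: each (reference, prediction)
pair in (0, 400] mg/dL falls in exactly one of five zones, A (clinically
accurate, within 20% or both hypoglycemic) through E (opposite-treatment
errors).  Zones are merged into a safe region (A+B) and an unsafe region
(C+D+E) for reporting.  Boundary inequalities follow the canonical published
grid, evaluated in the order A, E, C, D, with B as the remainder, so points
exactly on a boundary resolve deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PredictionSet", "MetricReport", "CEGResult",
    "evaluate_metrics", "clarke_zone", "clarke_zones", "ceg_analysis",
]

ZONES = ("A", "B", "C", "D", "E")


@dataclass
class PredictionSet:
    """Aligned reference and predicted glucose values, mg/dL."""

    refs: np.ndarray
    preds: np.ndarray
    context: dict = field(default_factory=dict)
    sex_labels: list[str] | None = None   # per-window labels for slicing

    def __post_init__(self):
        self.refs = np.asarray(self.refs, dtype=float)
        self.preds = np.asarray(self.preds, dtype=float)
        if self.refs.shape != self.preds.shape:
            raise ValueError("refs and preds must have equal length")

    @property
    def N(self) -> int:
        return len(self.refs)

    @property
    def residuals(self) -> np.ndarray:
        """Reference minus prediction, mg/dL."""
        return self.refs - self.preds


@dataclass
class MetricReport:
    rmse: float
    mad: float
    cod: float | None
    fit: float | None      # percent
    madp: float            # percent
    n: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mad": self.mad, "cod": self.cod,
                "fit": self.fit, "madp": self.madp, "n": self.n}


@dataclass
class CEGResult:
    counts: dict[str, int]
    percentages: dict[str, float]
    safe_percent: float        # zones A+B
    unsafe_percent: float      # zones C+D+E
    n: int


def evaluate_metrics(ps: PredictionSet) -> MetricReport:
    """Compute the five analytical metrics; COD/FIT are None on constant refs."""
    if ps.N < 2:
        raise ValueError("need at least 2 prediction pairs")
    refs, preds = ps.refs, ps.preds
    err = refs - preds
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mad = float(np.mean(np.abs(err)))
    ss_ref = float(np.sum((refs - refs.mean()) ** 2))
    if ss_ref > 0:
        cod = 1.0 - float(np.sum(err ** 2)) / ss_ref
        fit = (1.0 - rmse / np.sqrt(ss_ref / ps.N)) * 100.0
    else:
        cod = fit = None
    if np.any(refs <= 0):
        raise ValueError("MADP requires strictly positive reference values")
    madp = float(np.mean(np.abs(err) / refs) * 100.0)
    return MetricReport(rmse=rmse, mad=mad, cod=cod, fit=fit, madp=madp, n=ps.N)


def clarke_zones(refs: np.ndarray, preds: np.ndarray) -> np.ndarray:
    """Vectorized Clarke zone labels for arrays of (ref, pred) pairs."""
    refs = np.asarray(refs, dtype=float)
    preds = np.asarray(preds, dtype=float)
    if np.any((refs <= 0) | (refs > 400) | (preds <= 0) | (preds > 400)):
        raise ValueError("glucose values must lie in (0, 400] mg/dL")
    zone = np.full(refs.shape, "B", dtype="U1")
    a = (np.abs(preds - refs) <= 0.2 * refs) | ((refs <= 70) & (preds <= 70))
    e = ((refs >= 180) & (preds <= 70)) | ((refs <= 70) & (preds >= 180))
    c = (((refs >= 70) & (refs <= 290)) & (preds >= refs + 110)) | \
        (((refs >= 130) & (refs <= 180)) & (preds <= (7.0 / 5.0) * refs - 182))
    d = ((refs >= 240) & (preds >= 70) & (preds <= 180)) | \
        ((refs <= 175.0 / 3.0) & (preds >= 70) & (preds <= 180)) | \
        (((refs >= 175.0 / 3.0) & (refs <= 70)) & (preds >= (6.0 / 5.0) * refs))
    # evaluation order A -> E -> C -> D -> B decides boundary ties
    zone[d] = "D"
    zone[c] = "C"
    zone[e] = "E"
    zone[a] = "A"
    return zone


def clarke_zone(ref: float, pred: float) -> str:
    """Clarke Error Grid zone of a single (reference, prediction) pair."""
    return str(clarke_zones(np.array([ref]), np.array([pred]))[0])


def ceg_analysis(ps: PredictionSet) -> CEGResult:
    """Per-zone tallies and the merged safe (A+B) / unsafe (C+D+E) split.

    Model forecasts are unconstrained regression outputs and may leave the
    sensor's reporting range; they are clipped into (0, 400] before zoning,
    as an error-grid scatterplot would render them at its axis limits.
    References come from the sensor and must already be in range.
    """
    if ps.N < 1:
        raise ValueError("empty prediction set")
    labels = clarke_zones(ps.refs, np.clip(ps.preds, 1.0, 400.0))
    counts = {z: int(np.sum(labels == z)) for z in ZONES}
    pct = {z: 100.0 * counts[z] / ps.N for z in ZONES}
    safe = pct["A"] + pct["B"]
    return CEGResult(counts=counts, percentages=pct,
                     safe_percent=safe, unsafe_percent=100.0 - safe, n=ps.N)
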