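"""Cross-cohort generalization assessment.

A model trained on one cohort is evaluated on every cohort's test set,
producing a train-cohort x test-cohort matrix of RMSE values.  To ask
whether a model behaves *statistically* the same on foreign data, the
residuals (reference minus prediction) of each foreign-trained model on a
test cohort are compared with the residuals of the natively trained model
on that same test cohort by a two-sample Kolmogorov-Smirnov test at
alpha = 0.05; the diagonal compares a model with itself and its p-value is
1 by convention.

Foreign evaluation keeps normalization with the *test* cohort's own
training parameters: every model consumes z-scores, and mu/sigma travel
with the data, not with the model.

Demographic slicing re-evaluates one prediction set on its female and male
subsets separately, reporting per-slice RMSE and the pairwise KS p-values
(whole set vs F, whole set vs M, F vs M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .metrics import PredictionSet, evaluate_metrics

ALPHA = 0.05
EXACT_MAX_NM = 10_000        # exact KS p when n*m is at most this

__all__ = [
    "ResidualSet", "GeneralizationMatrix", "ks_two_sample",
    "cross_evaluate", "demographic_slices",
]


@dataclass
class ResidualSet:
    residuals: np.ndarray          # (G_i - Ghat_i), mg/dL
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.size == 0:
            raise ValueError("empty residual set")


@dataclass
class GeneralizationMatrix:
    """Long-format (architecture, train, test, horizon) -> (rmse, ks_p) grid."""

    cohorts: list[str]
    cells: dict[tuple[str, str, str, int], dict] = field(default_factory=dict)

    def cell(self, arch: str, train: str, test: str, horizon: int) -> dict:
        return self.cells[(arch, train, test, horizon)]

    def rows(self) -> list[dict]:
        return [
            {"arch": a, "train_cohort": tr, "test_cohort": te, "horizon": h, **v}
            for (a, tr, te, h), v in sorted(self.cells.items())
        ]

    def pivot(self, arch: str, horizon: int) -> dict[str, dict[str, str]]:
        """Test-cohort rows x train-cohort columns of 'RMSE (p)' strings."""
        table: dict[str, dict[str, str]] = {}
        for te in self.cohorts:
            table[te] = {}
            for tr in self.cohorts:
                c = self.cell(arch, tr, te, horizon)
                table[te][tr] = f"{c['rmse']:.2f} ({c['ks_p']:.2g})"
        return table


def ks_two_sample(a: ResidualSet | np.ndarray, b: ResidualSet | np.ndarray
                  ) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| and its p-value.

    The p-value is exact (enumeration over interleavings) when n*m <= 10,000
    and the asymptotic Kolmogorov distribution otherwise.  Identical samples
    give D = 0, p = 1.
    """
    x = a.residuals if isinstance(a, ResidualSet) else np.asarray(a, dtype=float)
    y = b.residuals if isinstance(b, ResidualSet) else np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    method = "exact" if x.size * y.size <= EXACT_MAX_NM else "asymp"
    result = stats.ks_2samp(x, y, method=method)
    return float(result.statistic), float(min(result.pvalue, 1.0))


def cross_evaluate(models: dict, test_sets: dict, architectures: list[str],
                   cohorts: list[str], horizons: list[int],
                   ks_stride: int = 1) -> GeneralizationMatrix:
    """Evaluate every trained model on every cohort's test set.

    Parameters
    ----------
    models
        ``(architecture, cohort, horizon) -> TrainedModel``; the model
        natively trained on that cohort.
    test_sets
        ``(cohort, horizon) -> (WindowSet, NormalizationParams)``; windows
        already normalized with the cohort's own training parameters.

    Each cell holds the de-normalized RMSE and the KS p-value of its
    residuals against the native (diagonal) residuals on the same test
    cohort; the diagonal p is 1.  ``ks_stride`` optionally thins the
    residual series before the KS comparison: consecutive sliding windows
    overlap almost entirely, so their residuals are strongly serially
    dependent and the KS test's iid assumption fails at large sample sizes;
    a stride of ~30 (2.5 hours) restores approximate independence.
    """
    from .training import predict     # local import to avoid a cycle

    matrix = GeneralizationMatrix(cohorts=list(cohorts))
    for arch in architectures:
        for h in horizons:
            native_residuals: dict[str, np.ndarray] = {}
            preds: dict[tuple[str, str], PredictionSet] = {}
            for te in cohorts:
                if (te, h) not in test_sets:
                    raise KeyError(f"missing test set for cohort {te}, horizon {h}")
                windows, params = test_sets[(te, h)]
                for tr in cohorts:
                    if (arch, tr, h) not in models:
                        raise KeyError(f"missing model for ({arch}, {tr}, {h})")
                    ps = predict(models[(arch, tr, h)], windows, params,
                                 context={"arch": arch, "train": tr,
                                          "test": te, "horizon": h})
                    preds[(tr, te)] = ps
                    if tr == te:
                        native_residuals[te] = ps.residuals
            for te in cohorts:
                for tr in cohorts:
                    ps = preds[(tr, te)]
                    rmse = evaluate_metrics(ps).rmse
                    if tr == te:
                        d, p = 0.0, 1.0
                    else:
                        d, p = ks_two_sample(ps.residuals[::ks_stride],
                                             native_residuals[te][::ks_stride])
                    matrix.cells[(arch, tr, te, h)] = {
                        "rmse": rmse, "ks_d": d, "ks_p": p,
                        "diagonal": tr == te,
                        "significant": (tr != te) and (p < ALPHA),
                    }
    return matrix


def demographic_slices(ps: PredictionSet) -> dict:
    """Per-sex RMSE and pairwise KS p-values for one prediction set.

    The prediction set must carry per-window sex labels ('F'/'M').  Slices
    with fewer than 2 windows are flagged rather than scored.
    """
    if ps.sex_labels is None or len(ps.sex_labels) != ps.N:
        raise ValueError("prediction set must carry one sex label per window")
    labels = np.asarray(ps.sex_labels)
    out: dict = {"n": {"FM": ps.N}}
    rmse: dict[str, float | None] = {}
    residuals: dict[str, np.ndarray] = {"FM": ps.residuals}
    rmse["FM"] = float(np.sqrt(np.mean(ps.residuals ** 2)))
    for slice_name, sex in (("F", "F"), ("M", "M")):
        mask = labels == sex
        out["n"][slice_name] = int(mask.sum())
        if mask.sum() < 2:
            rmse[slice_name] = None
            continue
        residuals[slice_name] = ps.residuals[mask]
        rmse[slice_name] = float(np.sqrt(np.mean(ps.residuals[mask] ** 2)))
    out["rmse"] = rmse
    ks: dict[str, float | None] = {}
    for name, (u, v) in {"FM_vs_F": ("FM", "F"), "FM_vs_M": ("FM", "M"),
                         "F_vs_M": ("F", "M")}.items():
        if u in residuals and v in residuals:
            ks[name] = ks_two_sample(residuals[u], residuals[v])[1]
        else:
            ks[name] = None
    out["ks_p"] = ks
    return out
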