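import itertools

import numpy as np
import pytest

import cgmbench as cb

# Canonical Clarke grid fixture: 25 (reference, prediction, zone) triples with
# zones derived from the published boundary inequalities by hand.
CLARKE_FIXTURE = [
    (100.0, 100.0, "A"),    # exact agreement
    (200.0, 240.0, "A"),    # exactly 20% high -> still A
    (60.0, 60.0, "A"),      # both hypoglycemic
    (400.0, 400.0, "A"),
    (200.0, 241.0, "B"),    # just over 20%
    (100.0, 180.0, "B"),
    (240.0, 181.0, "B"),    # one above the D band
    (120.0, 65.0, "B"),
    (72.0, 180.0, "B"),
    (150.0, 265.0, "C"),    # pred >= ref + 110
    (160.0, 40.0, "C"),     # pred <= 1.4*ref - 182
    (100.0, 210.0, "C"),    # boundary pred = ref + 110
    (179.0, 40.0, "C"),
    (120.0, 250.0, "C"),
    (250.0, 120.0, "D"),    # missed hyperglycemia
    (50.0, 120.0, "D"),     # missed hypoglycemia
    (70.0, 95.0, "D"),      # low-reference band, pred >= 1.2*ref
    (240.0, 180.0, "D"),    # boundary of the D band
    (300.0, 150.0, "D"),
    (58.0, 100.0, "D"),
    (50.0, 250.0, "E"),     # hypo read as hyper
    (250.0, 60.0, "E"),     # hyper read as hypo
    (300.0, 65.0, "E"),
    (180.0, 40.0, "E"),     # boundary ref = 180
    (58.0, 200.0, "E"),
]


def clarke_reference(ref: float, pred: float) -> str:
    """Independent scalar re-statement of the canonical zone inequalities."""
    if abs(pred - ref) <= 0.2 * ref or (ref <= 70 and pred <= 70):
        return "A"
    if (ref >= 180 and pred <= 70) or (ref <= 70 and pred >= 180):
        return "E"
    if (70 <= ref <= 290 and pred >= ref + 110) or \
       (130 <= ref <= 180 and pred <= (7.0 / 5.0) * ref - 182):
        return "C"
    if (ref >= 240 and 70 <= pred <= 180) or \
       (ref <= 175.0 / 3.0 and 70 <= pred <= 180) or \
       (175.0 / 3.0 <= ref <= 70 and pred >= (6.0 / 5.0) * ref):
        return "D"
    return "B"


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Sup-norm distance of the two empirical CDFs."""
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
    cdf_b = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_brute_force_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation p-value: fraction of interleavings with D >= D_obs."""
    d_obs = ks_statistic(a, b)
    pooled = np.sort(np.concatenate([a, b]))
    n, m = len(a), len(b)
    hits = total = 0
    for positions in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, bool)
        mask[list(positions)] = True
        d = ks_statistic(pooled[mask], pooled[~mask])
        hits += d >= d_obs - 1e-12
        total += 1
    return hits / total


@pytest.fixture(scope="session")
def small_profile() -> cb.CohortProfile:
    """An eight-patient, two-week open-loop cohort used across tests."""
    return cb.CohortProfile("small", 8, 2.0, basal_mean=150.0, basal_sd=48.0)


@pytest.fixture(scope="session")
def small_cohort(small_profile) -> list[cb.GlucoseTrace]:
    return cb.simulate_cohort(small_profile, 42)


@pytest.fixture(scope="session")
def small_datasets(small_cohort) -> dict:
    """Preprocessed windows (30- and 60-min horizons) for the small cohort."""
    return cb.build_datasets(small_cohort, L=24, horizons=[6, 12], seed=0)


@pytest.fixture(scope="session")
def hand_prediction_set() -> cb.PredictionSet:
    """The three-point fixture whose metric values are known in closed form."""
    return cb.PredictionSet(refs=[100.0, 150.0, 200.0], preds=[110.0, 140.0, 210.0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
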