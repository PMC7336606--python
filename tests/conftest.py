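import numpy as np
import pytest

from fundusfov.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def dr_phantom(default_config):
    """One grade-3 phantom (image, truth) used across detection tests."""
    return generate_phantom(default_config, grade=3, seed=7)


@pytest.fixture(scope="session")
def healthy_phantom(default_config):
    return generate_phantom(default_config, grade=0, seed=11)


@pytest.fixture(scope="session")
def fitted_phantoms(default_config):
    """Boundary + disc fits on 100 seeded phantoms (shared by the recovery
    property tests); grades cycle 0..4."""
    from fundusfov.fov import (DiscNotFound, BoundaryNotFound,
                               detect_optic_disc, fit_boundary_circle)
    out = []
    for seed in range(100):
        img, truth = generate_phantom(default_config, grade=seed % 5,
                                      seed=1000 + seed)
        try:
            boundary = fit_boundary_circle(img)
        except BoundaryNotFound:
            boundary = None
        disc = None
        if boundary is not None:
            try:
                disc = detect_optic_disc(img, boundary)
            except DiscNotFound:
                pass
        out.append((truth, boundary, disc))
    return out


def pair_count_auc(pos_scores, neg_scores):
    """Mann-Whitney AUC by brute-force pair enumeration (oracle)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_eer(scores, labels, n_thresholds=10 ** 6):
    """EER by sweeping evenly spaced thresholds (oracle).

    Decision: positive iff score >= threshold; positive class is label 0.
    Returns the midpoint of (FPR, FNR) at the threshold minimising their
    gap.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == 0)
    lo, hi = scores.min() - 1e-9, scores.max() + 1e-9
    ts = np.linspace(lo, hi, n_thresholds)
    pos_sorted = np.sort(scores[y])
    neg_sorted = np.sort(scores[~y])
    # tpr(t) = frac of positives >= t; fpr(t) = frac of negatives >= t
    tpr = 1.0 - np.searchsorted(pos_sorted, ts, side="left") / len(pos_sorted)
    fpr = 1.0 - np.searchsorted(neg_sorted, ts, side="left") / len(neg_sorted)
    fnr = 1.0 - tpr
    k = np.argmin(np.abs(fpr - fnr))
    return (fpr[k] + fnr[k]) / 2.0
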