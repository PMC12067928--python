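import numpy as np
import pytest

from decaysense import DecayTrace

LN2 = np.log(2.0)


def make_trace(half_life, amplitude=1000.0, plateau=0.0, times=None, noise_sd=0.0, rng=None):
    """Noiseless (or Gaussian-noised) one-phase decay trace on the default grid."""
    if times is None:
        times = np.arange(5.0, 181.0, 5.0)
    y = amplitude * np.exp(-LN2 * times / half_life) + plateau
    if noise_sd > 0:
        y = y + (rng or np.random.default_rng(0)).normal(0.0, noise_sd, size=len(times))
    return DecayTrace(times, y)


@pytest.fixture
def default_times():
    return np.arange(5.0, 181.0, 5.0)


def grid_search_decay_oracle(times, intensities, k_grid):
    """Independent decay-fit oracle: scan k on a grid, solving the two linear
    parameters (amplitude, plateau) exactly at each k, and return the
    (amplitude, k, plateau, sse) minimizing the SSE."""
    best = None
    y = np.asarray(intensities, float)
    for k in k_grid:
        design = np.column_stack([np.exp(-k * times), np.ones_like(times)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((design @ coef - y) ** 2))
        if best is None or sse < best[3]:
            best = (float(coef[0]), float(k), float(coef[1]), sse)
    return best


def pairwise_auc_oracle(truth, scores):
    """Brute-force AUC: fraction of positive-negative pairs where the positive
    outscores the negative, ties counted half."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, float)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
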