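import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def match_spikes(true_times, detected_times, tol_s=2e-3):
    """Greedy matching of detected to true spikes within a tolerance.

    Returns (n_true_positive, n_false_positive, n_false_negative).
    """
    true_times = np.asarray(true_times, dtype=float)
    detected_times = np.asarray(detected_times, dtype=float)
    used = np.zeros(detected_times.size, dtype=bool)
    tp = 0
    for t in true_times:
        if detected_times.size == 0:
            break
        d = np.abs(detected_times - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            tp += 1
    return tp, detected_times.size - tp, true_times.size - tp


def f1_score(true_times, detected_times, tol_s=2e-3):
    tp, fp, fn = match_spikes(true_times, detected_times, tol_s)
    precision = tp / max(1, tp + fp)
    recall = tp / max(1, tp + fn)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
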