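"""Independent reference computations used to cross-check the implementation.

Everything here is deliberately written from the defining formulas (loops,
explicit rank construction, per-template counting) rather than by calling
the code paths under test.
"""

import numpy as np
from scipy import stats as _stats


def time_domain_oracle(rr):
    """Direct accumulation formulas for the ten time-domain features."""
    n = len(rr)
    mean = sum(rr) / n
    sdnn = (sum((v - mean) ** 2 for v in rr) / n) ** 0.5
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    dmean = sum(d) / len(d)
    sdsd = (sum((v - dmean) ** 2 for v in d) / len(d)) ** 0.5
    rmssd = (sum(v * v for v in d) / len(d)) ** 0.5
    nn50 = sum(1 for v in d if abs(v) > 50)
    nn20 = sum(1 for v in d if abs(v) > 20)
    hr = [60000.0 / v for v in rr]
    hmean = sum(hr) / n
    sdhr = (sum((v - hmean) ** 2 for v in hr) / n) ** 0.5
    return {
        "MeanNN": mean, "SDNN": sdnn, "SDSD": sdsd, "NN50": nn50,
        "pNN50": nn50 / n, "NN20": nn20, "pNN20": nn20 / n,
        "RMSSD": rmssd, "MeanHR": hmean, "SDHR": sdhr,
    }


def sampen_oracle(x, m=2, r=None):
    """Brute-force O(n^2) double-loop template counting."""
    x = list(map(float, x))
    n = len(x)
    if r is None:
        mean = sum(x) / n
        sd = (sum((v - mean) ** 2 for v in x) / n) ** 0.5
        r = 0.2 * sd if sd > 0 else 1.0
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def sampen_oracle_rowwise(x, m=2, r=None):
    """Same counting as :func:`sampen_oracle`, one template row at a time
    (fast enough for hundreds of series while staying independent of the
    vectorized pairwise-distance implementation)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if r is None:
        sd = float(np.std(x))
        r = 0.2 * sd if sd > 0 else 1.0
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[: n - m]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    a = b = 0
    for i in range(len(tm) - 1):
        b += int((np.abs(tm[i + 1:] - tm[i]).max(axis=1) <= r).sum())
        a += int((np.abs(tm1[i + 1:] - tm1[i]).max(axis=1) <= r).sum())
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def spearman_oracle(x, y):
    """Average-rank Spearman via explicit rank construction + Pearson."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t statistic and p-value
    (b minus a, matching the high-minus-low convention)."""
    na, nb = len(a), len(b)
    va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (sum(b) / nb - sum(a) / na) / (sp2 * (1 / na + 1 / nb)) ** 0.5
    p = 2 * _stats.t.sf(abs(t), na + nb - 2)
    return t, p
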