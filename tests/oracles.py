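"""Independent reference implementations used to validate the pipeline.

Everything here is written from first principles (naive loops, closed
forms, exhaustive enumeration) and deliberately shares no code with the
package internals it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def naive_hampel(x, window, threshold, sampling_rate):
    """Per-sample median/MAD outlier replacement, O(n * w).

    Centered window of ``round(window * sampling_rate) // 2`` samples to
    either side, shrunk at the boundaries; robust SD = 1.4826 * MAD; all
    statistics on the original signal.
    """
    x = np.asarray(x, dtype=float)
    half = int(round(window * sampling_rate)) // 2
    y = x.copy()
    n = x.size
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = np.sort(x[lo:hi])
        m = win.size
        med = win[m // 2] if m % 2 else 0.5 * (win[m // 2 - 1] + win[m // 2])
        dev = np.sort(np.abs(x[lo:hi] - med))
        mad = dev[m // 2] if m % 2 else 0.5 * (dev[m // 2 - 1] + dev[m // 2])
        if abs(x[i] - med) > threshold * 1.4826 * mad:
            y[i] = med
    return y


def textbook_welch_amplitude(x, fs, nfft=256, overlap=0.5):
    """Segment -> Hamming window -> periodogram -> average, from the formula.

    One-sided power spectral density with the periodic Hamming window
    w[n] = 0.54 - 0.46 cos(2 pi n / N) and density normalization
    1 / (fs * sum(w^2)); interior bins doubled. Returns (freqs, amplitude).
    """
    x = np.asarray(x, dtype=float)
    step = nfft - int(round(nfft * overlap))
    nseg = (x.size - nfft) // step + 1
    n = np.arange(nfft)
    w = 0.54 - 0.46 * np.cos(2 * np.pi * n / nfft)
    scale = 1.0 / (fs * np.sum(w**2))
    psd = np.zeros(nfft // 2 + 1)
    for s in range(nseg):
        seg = x[s * step : s * step + nfft] * w
        spec = np.abs(np.fft.rfft(seg)) ** 2 * scale
        spec[1:-1] *= 2.0  # one-sided: double all but DC and Nyquist
        psd += spec
    psd /= nseg
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    return freqs, np.sqrt(psd)


def ols_closed_form(x, y):
    """Simple-regression coefficients from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def _average_ranks(values):
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_v = values[order]
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # average of positions i+1..j
        i = j
    return ranks


def exact_ranksum_p(a, b):
    """Two-sided rank-sum p by exhaustive enumeration of rank assignments.

    p = min(1, 2 * min(P(W <= w_obs), P(W >= w_obs))) where W is the rank
    sum of the first sample under uniformly random assignment of the pooled
    (average) ranks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = _average_ranks(pooled)
    n1 = a.size
    obs = ranks[:n1].sum()
    le = ge = total = 0
    eps = 1e-9
    for comb in combinations(range(pooled.size), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= obs + eps:
            le += 1
        if w >= obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le / total, ge / total))


def diagonal_lda_predict(Xtr, ytr, Xte):
    """Naive diagonal-covariance discriminant (pooled per-feature variances)."""
    Xtr = np.asarray(Xtr, dtype=float)
    classes = np.unique(ytr)
    n, k = len(ytr), len(classes)
    var = np.zeros(Xtr.shape[1])
    means = {}
    priors = {}
    for c in classes:
        Xi = Xtr[ytr == c]
        means[c] = Xi.mean(axis=0)
        priors[c] = Xi.shape[0] / n
        var += ((Xi - means[c]) ** 2).sum(axis=0)
    var /= max(n - k, 1)
    scores = np.empty((len(Xte), k))
    for j, c in enumerate(classes):
        mu = means[c]
        scores[:, j] = Xte @ (mu / var) - 0.5 * np.sum(mu**2 / var) + np.log(priors[c])
    return classes[np.argmax(scores, axis=1)]


def closed_form_lda_scores(Xtr, ytr, Xte):
    """Textbook LDA scores with an explicit pooled-covariance inverse."""
    Xtr = np.asarray(Xtr, dtype=float)
    classes = np.unique(ytr)
    n, k = len(ytr), len(classes)
    p = Xtr.shape[1]
    cov = np.zeros((p, p))
    means = []
    priors = []
    for c in classes:
        Xi = Xtr[ytr == c]
        mu = Xi.mean(axis=0)
        means.append(mu)
        priors.append(Xi.shape[0] / n)
        cov += (Xi - mu).T @ (Xi - mu)
    cov /= n - k
    inv = np.linalg.inv(cov)
    scores = np.empty((len(Xte), k))
    for j, (mu, pi) in enumerate(zip(means, priors)):
        scores[:, j] = Xte @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(pi)
    return classes, scores


def rank_pearson_spearman(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    rx = _average_ranks(np.asarray(x, dtype=float))
    ry = _average_ranks(np.asarray(y, dtype=float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
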