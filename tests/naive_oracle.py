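"""Independent, definitional re-implementation of the 28 local features.

Deliberately naive: explicit loops and direct formulas, sharing no code
with the package. Used to cross-check the vectorised implementation.
"""

from __future__ import annotations

import numpy as np

BANDS = [
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("low_beta", 13.0, 20.0),
    ("high_beta", 20.0, 30.0),
    ("low_gamma", 30.0, 45.0),
    ("high_gamma", 55.0, 90.0),
]
CANONICAL = {
    "delta": ["delta"],
    "theta": ["theta"],
    "alpha": ["alpha"],
    "beta": ["low_beta", "high_beta"],
    "gamma": ["low_gamma", "high_gamma"],
}
PAIRS = [
    ("delta", "theta"), ("delta", "alpha"), ("delta", "beta"),
    ("delta", "gamma"), ("theta", "alpha"), ("theta", "beta"),
    ("theta", "gamma"), ("alpha", "beta"), ("alpha", "gamma"),
    ("beta", "gamma"),
]


def naive_welch(x: np.ndarray, fs: float, nperseg: int, noverlap: int):
    """Welch PSD: mean of one-sided modified periodograms, Hamming window."""
    n = len(x)
    step = nperseg - noverlap
    w = 0.54 - 0.46 * np.cos(2.0 * np.pi * np.arange(nperseg) / nperseg)
    scale = 1.0 / (fs * np.sum(w * w))
    periodograms = []
    start = 0
    while start + nperseg <= n:
        seg = x[start : start + nperseg]
        seg = seg - seg.mean()  # constant detrend
        spec = np.fft.rfft(seg * w)
        p = scale * (spec.real**2 + spec.imag**2)
        p[1:-1] *= 2.0  # one-sided, even nperseg: keep DC and Nyquist
        periodograms.append(p)
        start += step
    psd = np.mean(periodograms, axis=0)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, psd


def naive_spectral(x: np.ndarray, fs: float = 200.0) -> dict[str, float]:
    freqs, psd = naive_welch(x, fs, nperseg=int(4 * fs), noverlap=int(2 * fs))
    df = freqs[1] - freqs[0]
    bp = {}
    for name, lo, hi in BANDS:
        total = 0.0
        for f, p in zip(freqs, psd):
            if lo <= f < hi:
                total += p * df
        bp[name] = total
    tot = sum(bp.values())
    out = {"total_power": np.log10(tot)}
    for name, _, _ in BANDS:
        out[f"relpow_{name}"] = bp[name] / tot
    canon = {c: sum(bp[m] for m in ms) for c, ms in CANONICAL.items()}
    for p, q in PAIRS:
        out[f"ratio_{p}_{q}"] = canon[p] / canon[q]
    return out


def naive_temporal(x: np.ndarray) -> dict[str, float]:
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    std = np.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    q75 = np.percentile(x, 75)
    q25 = np.percentile(x, 25)
    zc = sum(1 for i in range(n - 1) if x[i] * x[i + 1] < 0)
    d1 = np.diff(x)
    d2 = np.diff(d1)
    var0 = np.var(x)
    var1 = np.var(d1)
    var2 = np.var(d2)
    mob = np.sqrt(var1 / var0)
    return {
        "std": std,
        "iqr": q75 - q25,
        "skewness": m3 / m2**1.5,
        "kurtosis": m4 / m2**2 - 3.0,
        "zero_crossings": float(zc),
        "hjorth_mobility": mob,
        "hjorth_complexity": np.sqrt(var2 / var1) / mob,
    }


def naive_permutation_entropy(x: np.ndarray, order: int = 3) -> float:
    import math

    counts: dict[tuple, int] = {}
    for i in range(len(x) - order + 1):
        pattern = tuple(np.argsort(x[i : i + order], kind="stable"))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * np.log(p)
    return h / np.log(math.factorial(order))


def naive_higuchi(x: np.ndarray, kmax: int = 10) -> float:
    n = len(x)
    lk = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = list(range(m, n, k))
            lm = 0.0
            for a, b in zip(idx[:-1], idx[1:]):
                lm += abs(x[b] - x[a])
            n_m = len(idx) - 1
            lm *= (n - 1) / (n_m * k)
            lengths.append(lm / k)
        lk.append(float(np.mean(lengths)))
    slope, _ = np.polyfit(np.log(1.0 / np.arange(1, kmax + 1)), np.log(lk), 1)
    return float(slope)


def naive_petrosian(x: np.ndarray) -> float:
    d = np.diff(x)
    n_delta = sum(1 for i in range(len(d) - 1) if d[i] * d[i + 1] < 0)
    n = len(x)
    return np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta)))


def naive_all_features(x: np.ndarray, fs: float = 200.0) -> dict[str, float]:
    out = naive_spectral(x, fs)
    out.update(naive_temporal(x))
    out["permutation_entropy"] = naive_permutation_entropy(x)
    out["higuchi_fd"] = naive_higuchi(x)
    out["petrosian_fd"] = naive_petrosian(x)
    return out
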