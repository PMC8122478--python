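"""Independent brute-force reference implementations used as test oracles.

Everything here is written from first principles — explicit loops,
direct DFT sums, and a pyramid filter bank built from the published
Daubechies decomposition taps — deliberately avoiding the code paths
(and, where practical, the libraries) used by the package itself.
"""

from __future__ import annotations

import math

import numpy as np

# Published Daubechies decomposition filter taps (orthonormal family).
DB_TAPS = {
    "db1": (
        [0.7071067811865476, 0.7071067811865476],
        [-0.7071067811865476, 0.7071067811865476],
    ),
    "db4": (
        [-0.010597401785069032, 0.0328830116668852, 0.030841381835560764,
         -0.18703481171909309, -0.027983769416859854, 0.6308807679298589,
         0.7148465705529157, 0.2303778133088965],
        [-0.2303778133088965, 0.7148465705529157, -0.6308807679298589,
         -0.027983769416859854, 0.18703481171909309, 0.030841381835560764,
         -0.0328830116668852, -0.010597401785069032],
    ),
    "db7": (
        [0.00035371379997452024, -0.0018016407040474908, 0.0004295779729213665,
         0.01255099855609984, -0.01657454163066688, -0.03802993693501441,
         0.08061260915108308, 0.07130921926683026, -0.22403618499387498,
         -0.14390600392856498, 0.4697822874051931, 0.7291320908462351,
         0.3965393194819173, 0.07785205408500918],
        [-0.07785205408500918, 0.3965393194819173, -0.7291320908462351,
         0.4697822874051931, 0.14390600392856498, -0.22403618499387498,
         -0.07130921926683026, 0.08061260915108308, 0.03802993693501441,
         -0.01657454163066688, -0.01255099855609984, 0.0004295779729213665,
         0.0018016407040474908, 0.00035371379997452024],
    ),
}


# ---------------------------------------------------------------- time domain

def mav_oracle(x):
    return sum(abs(v) for v in x) / len(x)


def wamp_oracle(x, thr):
    return sum(1 for i in range(len(x) - 1) if abs(x[i + 1] - x[i]) > thr)


def zc_oracle(x, thr):
    return sum(
        1
        for i in range(len(x) - 1)
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= thr
    )


def wl_oracle(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def ssc_oracle(x, thr):
    return sum(
        1
        for i in range(1, len(x) - 1)
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > thr
    )


def rms_oracle(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def logvar_oracle(x, eps):
    m = sum(x) / len(x)
    var = sum((v - m) ** 2 for v in x) / len(x)
    return math.log(var + eps)


def ar_oracle(x, order=4):
    """Yule-Walker via explicitly formed biased autocovariances."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    r = np.array([np.sum(xc[: n - k] * xc[k:]) / n for k in range(order + 1)])
    R = np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)])
    return np.linalg.solve(R, r[1 : order + 1])


# ----------------------------------------------------------- frequency domain

def psd_oracle(x, rate):
    """One-sided Hann-tapered periodogram via a direct DFT sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    w = np.array([0.5 - 0.5 * math.cos(2 * math.pi * k / n) for k in range(n)])
    xw = x * w
    n_bins = n // 2 + 1
    freqs = np.array([k * rate / n for k in range(n_bins)])
    p = np.empty(n_bins)
    for k in range(n_bins):
        re = sum(xw[m] * math.cos(2 * math.pi * k * m / n) for m in range(n))
        im = -sum(xw[m] * math.sin(2 * math.pi * k * m / n) for m in range(n))
        val = (re * re + im * im) / (rate * np.sum(w * w))
        if 0 < k < n_bins - 1 or (k == n_bins - 1 and n % 2 == 1):
            val *= 2.0
        p[k] = val
    return freqs, p


def fd_features_oracle(x, rate, pr_split):
    f, p = psd_oracle(x, rate)
    total = p.sum()
    if total <= 0:
        return dict.fromkeys(("MDF", "MNF", "PR", "PKF", "MNP"), 0.0)
    cum = 0.0
    mdf = f[-1]
    for k in range(len(p)):
        cum += p[k]
        if cum >= 0.5 * total:
            mdf = f[k]
            break
    low = sum(p[k] for k in range(len(p)) if f[k] < pr_split)
    high = sum(p[k] for k in range(len(p)) if f[k] >= pr_split)
    return {
        "MDF": float(mdf),
        "MNF": float((f * p).sum() / total),
        "PR": float(low / high) if high > 0 else 0.0,
        "PKF": float(f[int(np.argmax(p))]),
        "MNP": float(p.mean()),
    }


# ------------------------------------------------------------------- wavelets

def dwt_step_oracle(x, lo, hi):
    """One analysis step: symmetric extension, convolution, dyadic downsample."""
    x = np.asarray(x, dtype=float)
    fl = len(lo)
    ext = np.concatenate([x[: fl - 1][::-1], x, x[-(fl - 1):][::-1]])
    ca = np.convolve(ext, lo, "valid")[1::2]
    cd = np.convolve(ext, hi, "valid")[1::2]
    return ca, cd


def dwt_details_oracle(x, basis, level=3):
    lo, hi = DB_TAPS[basis]
    ca = np.asarray(x, dtype=float)
    details = {}
    for lev in range(1, level + 1):
        ca, cd = dwt_step_oracle(ca, lo, hi)
        details[f"cD{lev}"] = cd
    return details


# -------------------------------------------------------- separability indices

def db_index_oracle(means, dispersions):
    L = len(means)
    total = 0.0
    for i in range(L):
        worst = -np.inf
        for j in range(L):
            if j == i:
                continue
            d = float(np.linalg.norm(np.asarray(means[i]) - np.asarray(means[j])))
            worst = max(worst, (dispersions[i] + dispersions[j]) / d)
        total += worst
    return total / L


def scattering_oracle(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n, d = values.shape
    grand = values.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for lab in sorted(set(labels.tolist())):
        pts = values[labels == lab]
        mu = pts.mean(axis=0)
        cov = np.zeros((d, d))
        for p in pts:
            cov += np.outer(p - mu, p - mu)
        sw += (pts.shape[0] / n) * cov / pts.shape[0]
        sb += (pts.shape[0] / n) * np.outer(mu - grand, mu - grand)
    return float(np.trace(sw) / np.trace(sb))


def res_oracle(means, stds):
    L = len(means)
    total, count = 0.0, 0
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            d = float(np.linalg.norm(np.asarray(means[i]) - np.asarray(means[j])))
            total += d / (0.5 * (stds[i] + stds[j]))
            count += 1
    return total / count


def stn_oracle(vals):
    vals = list(vals)
    m = sum(vals) / len(vals)
    return math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))


# --------------------------------------------------------------------- fusion

def plurality_oracle(labels):
    """Winning label; None when tied (caller handles ties separately)."""
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else None


def weighted_oracle(labels, weights):
    """Winning class; None when tied."""
    L = np.asarray(weights).shape[1]
    scores = [0.0] * L
    for j, lab in enumerate(labels):
        scores[lab - 1] += weights[j][lab - 1]
    best = max(scores)
    winners = [c + 1 for c, s in enumerate(scores) if s == best]
    return winners[0] if len(winners) == 1 else None


# -------------------------------------------------------------------- metrics

def macro_f1_oracle(cm):
    cm = np.asarray(cm, dtype=float)
    L = cm.shape[0]
    precisions, recalls = [], []
    for i in range(L):
        true_i = cm[i].sum()
        if true_i == 0:
            continue
        pred_i = cm[:, i].sum()
        precisions.append(cm[i, i] / pred_i if pred_i > 0 else 0.0)
        recalls.append(cm[i, i] / true_i)
    mp = sum(precisions) / len(precisions)
    mr = sum(recalls) / len(recalls)
    return 0.0 if mp + mr == 0 else 2 * mp * mr / (mp + mr)
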