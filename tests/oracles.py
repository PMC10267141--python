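"""Independent brute-force oracles, written directly from the textbook
definitions of each quantity and kept free of the package's vectorized code
paths (explicit per-sample loops, explicit phase unwrapping, explicit
step-up FDR)."""

from __future__ import annotations

import math

import numpy as np
import scipy.signal


def _trimmed_analytic(x: np.ndarray, trim_fraction: float) -> np.ndarray:
    z = scipy.signal.hilbert(np.asarray(x, float))
    k = int(round(trim_fraction * z.size))
    return z[k : z.size - k] if k else z


def brute_plv(x, y, trim_fraction=0.1) -> float:
    """PLV from explicitly unwrapped instantaneous phases."""
    zx = _trimmed_analytic(x, trim_fraction)
    zy = _trimmed_analytic(y, trim_fraction)
    phix = np.unwrap(np.angle(zx))
    phiy = np.unwrap(np.angle(zy))
    acc = 0 + 0j
    for d in phix - phiy:
        acc += complex(math.cos(d), math.sin(d))
    return abs(acc) / len(phix)


def _pearson_loop(a, b) -> float:
    am, bm = sum(a) / len(a), sum(b) / len(b)
    num = sum((x - am) * (y - bm) for x, y in zip(a, b))
    da = math.sqrt(sum((x - am) ** 2 for x in a))
    db = math.sqrt(sum((y - bm) ** 2 for y in b))
    return num / (da * db)


def brute_aec(x, y, trim_fraction=0.1) -> float:
    """|Pearson r| of Hilbert envelopes, accumulated sample by sample."""
    ex = np.abs(_trimmed_analytic(x, trim_fraction))
    ey = np.abs(_trimmed_analytic(y, trim_fraction))
    return abs(_pearson_loop(list(ex), list(ey)))


def brute_oaec(x, y, trim_fraction=0.1) -> float:
    """Orthogonalized AEC via per-sample 2-D least-squares regression.

    At each sample the complex value of one signal is regressed on the other
    signal's unit phasor (a real scale in the complex plane); the residual's
    magnitude is the orthogonalized envelope.
    """
    zx = _trimmed_analytic(x, trim_fraction)
    zy = _trimmed_analytic(y, trim_fraction)

    def ortho_env(za, zb):
        env = []
        for a, b in zip(za, zb):
            u = b / abs(b)  # unit phasor of the reference signal
            # least-squares real coefficient of a on u: Re(a * conj(u))
            coef = (a * u.conjugate()).real
            env.append(abs(a - coef * u))
        return env

    r1 = _pearson_loop(ortho_env(zy, zx), list(np.abs(zx)))
    r2 = _pearson_loop(ortho_env(zx, zy), list(np.abs(zy)))
    return abs((r1 + r2) / 2.0)


def brute_fdr_bh(pvals) -> list[float]:
    """Benjamini-Hochberg step-up, written from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def brute_fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = hyper(a)
    return sum(hyper(k) for k in range(lo, hi + 1) if hyper(k) <= p_obs * (1 + 1e-9))


def brute_auc_rank(strengths, labels) -> float:
    """AUC as the Mann-Whitney probability (ties counted half)."""
    pos = [s for s, l in zip(strengths, labels) if l]
    neg = [s for s, l in zip(strengths, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
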