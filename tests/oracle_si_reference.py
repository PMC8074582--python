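"""Independent brute-force SI oracle (node-by-node Bernoulli loop).

Not part of the test suite; run directly to regenerate the frozen expected
values used by the tests:
  * K50, r=0.5: Monte-Carlo interval for mean tau (10^4 runs)
  * K30, r=0.02: oracle conductance fit (10^4 runs)
  * K100, r=0.01: sup-norm of mean curve vs best-fit logistic (200 runs)
"""
import math
import random
import sys

import numpy as np


def si_complete(n, r, seed, max_steps=10000):
    rng = random.Random(seed)
    infected = 1
    counts = [1]
    steps = 0
    while infected < n and steps < max_steps:
        new = 0
        p = 1 - (1 - r) ** infected
        for _ in range(n - infected):
            if rng.random() < p:
                new += 1
        infected += new
        steps += 1
        counts.append(infected)
    return steps, counts


def logistic(N, Cr, I0, t):
    return N * I0 / (I0 + (N - I0) * np.exp(-Cr * N * t))


def fit_C(curve, N, r):
    t = np.arange(len(curve))
    I0 = curve[0]
    best, bestC = None, None
    for C in np.geomspace(1e-6, 1, 4000):
        res = np.sum((curve - logistic(N, C * r, I0, t)) ** 2)
        if best is None or res < best:
            best, bestC = res, C
    return bestC, best


if __name__ == "__main__":
    # K50 r=0.5 mean tau
    taus = [si_complete(50, 0.5, s)[0] for s in range(10000)]
    print("K50 r=0.5 mean tau = %.3f sd %.3f" % (np.mean(taus), np.std(taus)))

    # K30 r=0.02 conductance
    runs = [si_complete(30, 0.02, 10_000 + s)[1] for s in range(10000)]
    horizon = max(len(c) for c in runs)
    padded = [c + [c[-1]] * (horizon - len(c)) for c in runs]
    curve = np.mean(padded, axis=0)
    C, res = fit_C(curve, 30, 0.02)
    print("K30 r=0.02 oracle C = %.5f (residual %.2f)" % (C, res))

    # K100 r=0.01 sup-norm, 200 runs
    runs = [si_complete(100, 0.01, 20_000 + s)[1] for s in range(200)]
    horizon = max(len(c) for c in runs)
    padded = [c + [c[-1]] * (horizon - len(c)) for c in runs]
    curve = np.mean(padded, axis=0)
    C, res = fit_C(curve, 100, 0.01)
    sup = np.max(np.abs(curve - logistic(100, C * 0.01, curve[0], np.arange(len(curve)))))
    print("K100 r=0.01 fitted C = %.5f supnorm/N = %.4f" % (C, sup / 100))
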