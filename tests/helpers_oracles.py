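"""Independent brute-force reference implementations used as test oracles.

Deliberately written as plain sample-by-sample loops, sharing no code
with the package's vectorized feature path.
"""

import math

import numpy as np


def brute_awdiff(a: np.ndarray, nw: int) -> np.ndarray:
    """Per-window norm of per-axis (max - min) ranges, looped."""
    n = a.shape[0]
    out = []
    for j in range(n - nw + 1):
        total = 0.0
        for axis in range(3):
            w = [a[i, axis] for i in range(j, j + nw)]
            total += (max(w) - min(w)) ** 2
        out.append(math.sqrt(total))
    return np.array(out)


def brute_features(a: np.ndarray, k0: int, nw: int, vertical_axis: int) -> dict:
    """Direct loop evaluation of the six window statistics."""
    w = a[k0 : k0 + nw]
    smv = [math.sqrt(x * x + y * y + z * z) for x, y, z in w]
    mu_smv = sum(smv) / nw
    sigma_smv = math.sqrt(sum((s - mu_smv) ** 2 for s in smv) / nw)
    mu_smvdiff = sum(abs(smv[i + 1] - smv[i]) for i in range(nw - 1)) / nw
    theta_sum = 0.0
    for i in range(nw - 1):
        denom = smv[i] * smv[i + 1]
        if denom == 0:
            continue
        dot = sum(w[i, ax] * w[i + 1, ax] for ax in range(3))
        theta_sum += math.acos(max(-1.0, min(1.0, dot / denom)))
    mu_theta = theta_sum / nw
    perp = [ax for ax in range(3) if ax != vertical_axis]
    mu_ap = sum(
        math.sqrt(w[i, perp[0]] ** 2 + w[i, perp[1]] ** 2) for i in range(nw)
    ) / nw
    aw = brute_awdiff(a, nw)
    return {
        "mu_smv": mu_smv,
        "awdiff_max": float(max(aw)),
        "sigma_smv": sigma_smv,
        "mu_theta": mu_theta,
        "mu_smvdiff": mu_smvdiff,
        "mu_ap": mu_ap,
        "k0": int(np.argmax(aw)),
    }
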