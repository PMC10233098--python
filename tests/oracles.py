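"""Independent brute-force oracles, written from first principles in plain
Python (no numpy vectorization), deliberately separate from the package's
code paths."""
from __future__ import annotations

import math


def _sd(values):
    n = len(values)
    if n < 2:
        return 0.0
    m = sum(values) / n
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


def _local_max_indices(series):
    return [i for i in range(1, len(series) - 1)
            if series[i] > series[i - 1] and series[i] > series[i + 1]]


def oracle_features(t, x, y, peaks="local"):
    """Recompute the 12 kinematic features with straightforward loops."""
    n = len(t)
    dt = t[1] - t[0]
    speeds = [math.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) / dt for i in range(n - 1)]
    accels = [(speeds[i + 1] - speeds[i]) / dt for i in range(len(speeds) - 1)]

    # turning angles between successive nonzero displacements
    disps = []
    for i in range(n - 1):
        dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
        if math.hypot(dx, dy) > 0:
            disps.append((dx, dy))
    dc = []
    for (ax, ay), (bx, by) in zip(disps[:-1], disps[1:]):
        dot = ax * bx + ay * by
        na, nb = math.hypot(ax, ay), math.hypot(bx, by)
        c = max(-1.0, min(1.0, dot / (na * nb)))
        dc.append(math.acos(c) / dt)

    length = sum(math.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) for i in range(n - 1))
    chord = math.hypot(x[-1] - x[0], y[-1] - y[0])

    def peak(series, kind):
        if peaks == "global":
            return max(series) if kind == "max" else min(series)
        if kind == "max":
            idx = _local_max_indices(series)
        else:
            neg = [-v for v in series]
            idx = _local_max_indices(neg)
        if not idx:
            return max(series) if kind == "max" else min(series)
        return sum(series[i] for i in idx) / len(idx)

    return {
        "MeanSpeed": sum(speeds) / len(speeds),
        "MaxSpeed": peak(speeds, "max"),
        "MinSpeed": peak(speeds, "min"),
        "sdSpeed": _sd(speeds),
        "MeanAcceleration": sum(accels) / len(accels),
        "MaxAcceleration": peak(accels, "max"),
        "MinAcceleration": peak(accels, "min"),
        "sdAcceleration": _sd(accels),
        "STH": min(chord / length, 1.0),
        "DC": sum(dc) / len(dc),
        "sdDC": _sd(dc),
        "MeanLength": length,
    }


def oracle_kl_1d(mu, sigma):
    """Numerical quadrature of KL(N(mu, sigma^2), N(0, 1)) in one dimension."""
    from scipy.integrate import quad

    def integrand(z):
        q = math.exp(-0.5 * ((z - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        if q < 1e-300:
            return 0.0
        p = math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
        return q * math.log(q / p)

    val, _ = quad(integrand, mu - 12 * sigma, mu + 12 * sigma, limit=200)
    return val
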