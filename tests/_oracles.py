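"""Independent brute-force oracles for the response-curve descriptors.

Deliberately naive pure-Python implementations (explicit loops, sorted-list
medians) kept separate from the package code paths they are used to check.
All operate on a plain list ``curve`` with half-open phase windows
``{"baseline": (lo, hi), "during": ..., "after": ...}`` at 1 Hz and exact
point evaluation (no median smoothing window).
"""


def median(values):
    s = sorted(values)
    n = len(s)
    if n == 0:
        raise ValueError("empty")
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def r0(curve, phases):
    lo, hi = phases["baseline"]
    return median(curve[lo:hi])


def point(curve, phases, phase, offset):
    lo, hi = phases[phase]
    idx = lo + int(round(offset))
    if not lo <= idx <= hi:
        raise ValueError("out of window")
    return curve[min(idx, hi - 1)]


def feat_A(curve, phases, t):
    return point(curve, phases, "during", t) / r0(curve, phases)


def feat_B(curve, phases, t):
    return point(curve, phases, "during", t) - r0(curve, phases)


def feat_C(curve, phases, t):
    return point(curve, phases, "after", t) - r0(curve, phases)


def feat_D(curve, phases):
    lo, hi = phases["during"]
    best = curve[lo]
    for v in curve[lo:hi]:
        if v < best:
            best = v
    return best


def feat_E(curve, phases, t1, t2, t3):
    v1 = point(curve, phases, "during", t1)
    v2 = point(curve, phases, "during", t2)
    v3 = point(curve, phases, "during", t3)
    return (v3 - v2) / (v2 - v1)


def feat_F(curve, phases, t1, t2):
    return point(curve, phases, "during", t2) - point(curve, phases, "during", t1)


def feat_G_unrolled(curve, phases, alpha):
    """min_k y[k] with y[k] = alpha * sum_j (1-alpha)^(k-j) (x[j]-x[j-1])."""
    stop = phases["during"][1]
    x = curve[:stop]
    best = 0.0  # y[0] = 0
    for k in range(1, len(x)):
        y_k = 0.0
        for j in range(1, k + 1):
            y_k += alpha * (1.0 - alpha) ** (k - j) * (x[j] - x[j - 1])
        if y_k < best:
            best = y_k
    return best


def feat_H(curve, phases):
    lo, hi = phases["during"]
    m = feat_D(curve, phases)
    return r0(curve, phases) / m
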