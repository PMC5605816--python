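"""Independent brute-force oracles used by several test modules.

Everything here is written with explicit Python loops and plain sign
comparisons so that it shares no dynamics code with the package.
"""

import numpy as np


def sign_ge(x: float) -> int:
    return 1 if x >= 0 else -1


def sync_step(W, s, bias=None):
    """One synchronous threshold update via explicit double sums."""
    n = len(s)
    out = []
    for i in range(n):
        h = sum(float(W[i][j]) * int(s[j]) for j in range(n))
        if bias is not None:
            h += float(bias[i])
        out.append(sign_ge(h))
    return np.array(out, dtype=np.int8)


def converge(W, s, bias=None, max_sweeps=50):
    """Iterate sync_step to a fixed point or a detected period-2 cycle."""
    prev = np.array(s, dtype=np.int8)
    prev_prev = None
    for _ in range(max_sweeps):
        new = sync_step(W, prev, bias)
        if np.array_equal(new, prev):
            return new
        if prev_prev is not None and np.array_equal(new, prev_prev):
            return new
        prev_prev, prev = prev, new
    return prev


def staged_recovery(A_inj, B, C, D, cue, max_sweeps=50):
    """Hand evaluation of the five recovery stages (clamped protocol).

    Returns the per-stage original and auxiliary states as a dict mirroring
    the trace layout of the package's recovery routine.
    """
    trace = {}
    s_o = converge(A_inj, cue, max_sweeps=max_sweeps)
    trace["inj1"] = (s_o.copy(), None)

    readout = [sum(float(C[i][j]) * int(s_o[j]) for j in range(len(s_o)))
               for i in range(len(C))]
    s_a = np.array([sign_ge(h) for h in readout], dtype=np.int8)
    trace["inj2"] = (s_o.copy(), s_a.copy())

    s_a = converge(D, s_a, bias=readout, max_sweeps=max_sweeps)
    trace["inj3"] = (s_o.copy(), s_a.copy())

    s_a = converge(D, s_a, max_sweeps=max_sweeps)
    trace["inj4"] = (s_o.copy(), s_a.copy())

    feedback = [sum(float(B[i][j]) * int(s_a[j]) for j in range(len(s_a)))
                for i in range(len(s_o))]
    s_o = converge(A_inj, s_o, bias=feedback, max_sweeps=max_sweeps)
    trace["inj5"] = (s_o.copy(), s_a.copy())
    return trace
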