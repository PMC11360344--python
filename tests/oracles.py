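"""Naive reference implementations used as independent test oracles.

Everything here is written for obviousness, not speed: plain Python loops,
direct transcriptions of the rules. The production code must agree with
these on randomized inputs; the two code paths share no helper code.
"""

from __future__ import annotations

import math


def bandpass_reference(signal, b, a, steady_start=False):
    """Direct-form I difference equation, sample by sample.

    With ``steady_start`` the prehistory (n < 0) is taken as the constant
    first sample and the corresponding constant output x0 * sum(b)/sum(a)
    — i.e. the filter has been fed x0 forever. Otherwise prehistory is zero.
    """
    b = list(b)
    a = list(a)
    a0 = a[0]
    b = [bi / a0 for bi in b]
    a = [ai / a0 for ai in a]
    if steady_start and signal:
        x0 = signal[0]
        y0 = x0 * sum(b) / sum(a)
    else:
        x0 = y0 = 0.0
    y = []
    for n in range(len(signal)):
        acc = 0.0
        for k in range(len(b)):
            acc += b[k] * (signal[n - k] if n - k >= 0 else x0)
        for k in range(1, len(a)):
            acc -= a[k] * (y[n - k] if n - k >= 0 else y0)
        y.append(acc)
    return y


def counts_reference(axis, fs_in, b, a, *, fs_filter=30.0, fs_decimated=10.0,
                     epoch_length_s=60.0, scale=17.127404, ceiling=128.0, deadband=4.0):
    """Per-sample transcription of the counts chain for one axis.

    Down-sample (every k-th sample, truncated to floor(n*out/in)), band-pass,
    scale/rectify/threshold, down-sample to 10 Hz, floor and sum per epoch.
    """
    step = fs_in / fs_filter
    assert abs(step - round(step)) < 1e-9, "reference only handles integer ratios"
    step = int(round(step))
    n_out = int(math.floor(len(axis) * fs_filter / fs_in))
    down = [axis[i * step] for i in range(n_out)]

    filt = bandpass_reference(down, b, a, steady_start=True)

    thresh = []
    for v in filt:
        u = abs(v) * scale
        if u > ceiling:
            u = ceiling
        if u < deadband:
            u = 0.0
        thresh.append(u)

    step2 = int(round(fs_filter / fs_decimated))
    dec = thresh[::step2]

    block = int(round(fs_decimated * epoch_length_s))
    counts = []
    for e in range(len(dec) // block):
        total = 0
        for v in dec[e * block : (e + 1) * block]:
            total += int(math.floor(v))
        counts.append(total)
    return counts


def troiano_reference(cpm, min_len=60, max_interruption=2, ceiling=100):
    """Brute-force: try every start, extend while the predicate holds, mark
    qualifying intervals. A qualifying interval starts and ends on a zero
    minute, contains no minute >= ceiling, and no run of more than
    ``max_interruption`` consecutive minutes with 0 < count < ceiling.
    """
    n = len(cpm)
    nonwear = [False] * n
    for start in range(n):
        if cpm[start] != 0:
            continue
        last_zero = start
        run = 0
        for k in range(start + 1, n):
            c = cpm[k]
            if c == 0:
                last_zero = k
                run = 0
            elif c < ceiling:
                run += 1
                if run > max_interruption:
                    break
            else:
                break
        if last_zero - start + 1 >= min_len:
            for i in range(start, last_zero + 1):
                nonwear[i] = True
    return [0 if nw else 1 for nw in nonwear]


def steps_reference(scaled, descend=-4.0, ascend=4.0):
    """Literal two-state machine with explicit 'having been' bookkeeping."""
    ARMED, UNARMED = "armed", "unarmed"
    state = UNARMED
    been_nonneg = True   # satisfied at start by definition
    been_nonpos = False
    steps = 0
    for v in scaled:
        if state == UNARMED:
            if v >= 0:
                been_nonneg = True
            if been_nonneg and v <= descend:
                state = ARMED
                been_nonpos = True  # v <= descend < 0
                been_nonneg = False
        else:
            if v <= 0:
                been_nonpos = True
            if been_nonpos and v >= ascend:
                steps += 1
                state = UNARMED
                been_nonneg = True  # v >= ascend > 0
                been_nonpos = False
    return steps


def classify_reference(cpm, boundaries):
    """Linear scan over (label, lo, hi) intervals."""
    for label, lo, hi in boundaries:
        if cpm >= lo and (hi is None or cpm <= hi):
            return label
    raise AssertionError(f"no interval contains {cpm}")
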