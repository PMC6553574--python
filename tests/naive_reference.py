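"""Deliberately naive, loop-based reference for the per-cycle feature chain.

Kept free of any wavepac internals (only scipy's firwin for the filter
design) so it can serve as an independent oracle for the vectorized
pipeline: explicit scans for zerocrossings, explicit per-sample loops for
extrema, sharpness and steepness.
"""

import numpy as np
from scipy.signal import firwin


def naive_cycle_table(raw, fs, f_lo=13.0, f_hi=30.0, order_ms=231.0, width=3):
    """Returns a list of dicts, one per complete cycle, mirroring the
    pipeline's cycle-table columns (without validity bookkeeping)."""
    raw = np.asarray(raw, dtype=float)
    taps = round(order_ms * fs / 1000.0)
    if taps % 2 == 0:
        taps += 1
    h = firwin(taps, [f_lo, f_hi], pass_zero=False, fs=fs, window="hamming")
    filt = np.convolve(raw, h, mode="same")

    rising, falling = [], []
    for i in range(len(filt) - 1):
        if filt[i] < 0 and filt[i + 1] >= 0:
            rising.append(i)
        elif filt[i] >= 0 and filt[i + 1] < 0:
            falling.append(i)
    if not rising:
        return []
    falling = [f for f in falling if f > rising[0]]
    n = min(len(rising) - 1, len(falling))

    rows = []
    prev_trough = None
    for k in range(n):
        r, f, r2 = rising[k], falling[k], rising[k + 1]
        peak = r
        for i in range(r, f):
            if raw[i] > raw[peak]:
                peak = i
        trough = f
        for i in range(f, r2):
            if raw[i] < raw[trough]:
                trough = i

        if width <= peak < len(raw) - width:
            peak_sharp = ((raw[peak] - raw[peak - width])
                          + (raw[peak] - raw[peak + width])) / 2.0
        else:
            peak_sharp = np.nan
        if width <= trough < len(raw) - width:
            trough_sharp = ((raw[trough - width] - raw[trough])
                            + (raw[trough + width] - raw[trough])) / 2.0
        else:
            trough_sharp = np.nan

        rise_steep = np.nan
        if prev_trough is not None and peak > prev_trough:
            best = -np.inf
            for i in range(prev_trough, peak):
                slope = raw[i + 1] - raw[i]
                if slope > best:
                    best = slope
            rise_steep = best
        decay_steep = np.nan
        if trough > peak:
            best = -np.inf
            for i in range(peak, trough):
                slope = abs(raw[i + 1] - raw[i])
                if slope > best:
                    best = slope
            decay_steep = best

        rows.append({
            "rise_zc": r, "fall_zc": f, "peak_idx": peak, "trough_idx": trough,
            "peak_sharp": peak_sharp, "trough_sharp": trough_sharp,
            "rise_steep": rise_steep, "decay_steep": decay_steep,
        })
        prev_trough = trough
    return rows
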