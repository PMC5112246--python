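"""Independent reference implementations used to cross-check the pipeline.

Deliberately naive: pointwise weighted polyfit for the smoother and a plain
python scan for run detection, sharing no code with the package internals.
"""

import numpy as np


def naive_loess_smooth(pos, values, cluster_ids, bandwidth=1000, min_probes=7):
    """Per-probe tricube-weighted local linear fit (running mean / passthrough
    for small clusters), evaluated one probe at a time."""
    out = np.empty_like(values, dtype=float)
    for cid in np.unique(cluster_ids):
        idx = np.flatnonzero(cluster_ids == cid)
        p, v = pos[idx].astype(float), values[idx]
        k = len(idx)
        if k <= 2:
            out[idx] = v
        elif k < min_probes:
            for i in range(k):
                out[idx[i]] = v[max(0, i - 1) : i + 2].mean()
        else:
            for i in range(k):
                u = np.abs(p - p[i]) / bandwidth
                w = np.where(u < 1, (1 - u**3) ** 3, 0.0)
                active = w > 0
                coeffs = np.polyfit(p[active], v[active], 1, w=np.sqrt(w[active]))
                out[idx[i]] = np.polyval(coeffs, p[i])
    return out


def naive_bump_areas(smoothed, cluster_ids, upper, lower):
    """Areas of maximal same-sign threshold exceedance runs, by plain scan."""
    areas = []
    current, sign = 0.0, 0
    prev_cluster = None
    for value, cid in zip(smoothed, cluster_ids):
        s = 1 if value > upper else (-1 if value < lower else 0)
        if s != 0 and s == sign and cid == prev_cluster:
            current += abs(value)
        else:
            if sign != 0:
                areas.append(current)
            current, sign = (abs(value), s) if s != 0 else (0.0, 0)
        prev_cluster = cid
    if sign != 0:
        areas.append(current)
    return areas
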