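"""Independent brute-force oracles used by the test suite."""

import numpy as np


def brute_force_otsu_mask(values, roi):
    """Exhaustive between-class-variance maximizer over candidate thresholds
    (midpoints between consecutive sorted unique ROI values)."""
    vals = values[roi]
    uniq = np.unique(vals)
    best_thr, best_var = None, -1.0
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        t = (lo + hi) / 2.0
        w1 = np.mean(vals <= t)
        w2 = 1.0 - w1
        if w1 == 0 or w2 == 0:
            continue
        var = w1 * w2 * (vals[vals > t].mean() - vals[vals <= t].mean()) ** 2
        if var > best_var:
            best_var, best_thr = var, t
    return (values > best_thr) & roi


def flood_fill_components(mask, connectivity):
    """BFS connected components; returns a set of frozensets of pixels."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy, dx in offsets:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] \
                                and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                comps.append(frozenset(comp))
    return set(comps)
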