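"""Independent brute-force oracles shared by the test modules.

Everything here is deliberately slow and explicit — permutation search and
all-pairs loops — so it shares no code path with the implementation it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def reference_clearmot(gt_frames, hyp_frames, threshold):
    """Readable multi-object-tracking bookkeeping oracle.

    Per frame: keep surviving previous correspondences, then match the rest
    by exhaustive minimum-distance permutation search (maximum cardinality
    first).  Counts FN/FP/IDSW, ground truth, matches and distances.
    """
    prior, last = {}, {}
    fn = fp = idsw = gt_total = matches = 0
    dist_sum = 0.0
    for gt_boxes, hyps in zip(gt_frames, hyp_frames):
        gt_pos = {g[0]: np.array(g[1:3]) for g in gt_boxes}
        hyp_pos = {h[0]: np.array(h[1:3]) for h in hyps}
        new = {}
        for gid, hid in prior.items():
            if gid in gt_pos and hid in hyp_pos:
                if np.hypot(*(gt_pos[gid] - hyp_pos[hid])) <= threshold:
                    new[gid] = hid
        free_g = [g for g in gt_pos if g not in new]
        free_h = [h for h in hyp_pos if h not in set(new.values())]
        best = None
        k = min(len(free_g), len(free_h))
        for subset in itertools.combinations(free_g, k):
            for perm in itertools.permutations(free_h, k):
                pairs = [
                    (g, h)
                    for g, h in zip(subset, perm)
                    if np.hypot(*(gt_pos[g] - hyp_pos[h])) <= threshold
                ]
                cost = sum(
                    np.hypot(*(gt_pos[g] - hyp_pos[h])) for g, h in pairs
                )
                key = (-len(pairs), cost)
                if best is None or key < best[0]:
                    best = (key, pairs)
        for g, h in best[1] if best else []:
            new[g] = h
        for gid, hid in new.items():
            if gid in last and last[gid] != hid:
                idsw += 1
            last[gid] = hid
            matches += 1
            dist_sum += float(np.hypot(*(gt_pos[gid] - hyp_pos[hid])))
        fn += len(gt_pos) - len(new)
        fp += len(hyp_pos) - len(new)
        gt_total += len(gt_pos)
        prior = new
    return fn, fp, idsw, gt_total, matches, dist_sum


def brute_force_assignment(cost: np.ndarray, gate: float):
    """Max-cardinality, min-cost gated matching by exhaustive search."""
    na, nb = cost.shape
    best_key, best_pairs = None, []
    k = min(na, nb)
    for subset in itertools.combinations(range(na), k):
        for perm in itertools.permutations(range(nb), k):
            pairs = [
                (i, j) for i, j in zip(subset, perm) if cost[i, j] <= gate
            ]
            c = sum(cost[i, j] for i, j in pairs)
            key = (-len(pairs), c)
            if best_key is None or key < best_key:
                best_key, best_pairs = key, pairs
    return best_pairs, (-best_key[0], best_key[1])


def brute_force_stay_points(xy: np.ndarray, times: np.ndarray, radius, min_dur):
    """Anchor-scan stay points with plain loops."""
    out = []
    i, n = 0, len(xy)
    while i < n:
        j = i + 1
        while j < n and np.hypot(*(xy[j] - xy[i])) <= radius:
            j += 1
        if times[j - 1] - times[i] >= min_dur:
            out.append((float(times[i]), float(times[j - 1])))
            i = j
        else:
            i += 1
    return out
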