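"""Independent brute-force oracles used to cross-check the pipeline.

The reading-measure oracle below walks an association sequence with plain
Python loops, translating each measure definition literally:

* gaze duration: dwell summed over the consecutive run starting at the
  first encounter, until any association off the unit;
* go-past time: everything from first encounter up to (excluding) the first
  association strictly to the right; missing if never passed rightward;
* total duration: all dwell on the unit;
* FPReg: whether the association that ends the first pass lies to the left;
  missing if the trial ends during the first pass;
* RegIn: whether the unit is fixated again after some fixation to its
  right; 0 if fixated but never regressed into, missing if never fixated.

It deliberately shares no code with motr.trajectory.
"""

from __future__ import annotations

import math


def oracle_measures(units, durations, all_units):
    """Five reading measures per unit, computed by literal definition."""
    n = len(units)
    out = {}
    for u in all_units:
        idx = [i for i, x in enumerate(units) if x == u]
        if not idx:
            out[u] = dict(
                gaze_duration=math.nan, go_past=math.nan,
                total_duration=math.nan, fp_reg=math.nan, reg_in=math.nan,
            )
            continue
        f = idx[0]
        k = f
        gaze = 0.0
        while k < n and units[k] == u:
            gaze += durations[k]
            k += 1
        if k >= n:
            fp_reg = math.nan
        else:
            fp_reg = 1.0 if units[k] < u else 0.0
        g = None
        for i in range(f, n):
            if units[i] > u:
                g = i
                break
        go_past = sum(durations[f:g]) if g is not None else math.nan
        total = sum(durations[i] for i in idx)
        reg_in = 0.0
        seen_right = False
        for i in range(n):
            if units[i] > u and i >= f:
                seen_right = True
            elif units[i] == u and seen_right:
                reg_in = 1.0
        out[u] = dict(
            gaze_duration=gaze, go_past=go_past, total_duration=total,
            fp_reg=fp_reg, reg_in=reg_in,
        )
    return out


def random_association_sequence(rng, max_units=8, max_assocs=30):
    """A random unit walk with runs, jumps and regressions."""
    n_units = int(rng.integers(2, max_units + 1))
    n = int(rng.integers(1, max_assocs + 1))
    units = rng.integers(1, n_units + 1, size=n).tolist()
    durations = rng.uniform(50.0, 600.0, size=n).tolist()
    return units, durations, list(range(1, n_units + 1))
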