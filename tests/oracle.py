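"""Independent brute-force planning oracle for cross-checking the planner.

Re-derives everything from raw tissue/air volumes with plain loops: option
matrix, fraction windows, volume cap, HI floor, least-diseased removal,
combined-TAR minimum with the 0.30-point near-tie rule broken by distance
to the 110% target, and lexicographic residual tie-break.  Shares only the
LungModel data container with the implementation under test.
"""

from itertools import combinations


def _tar(t, a):
    return 100.0 * t / a


def _volumes(model, seg):
    if seg == "LB1+2":
        s1, s2 = model.segments["LB1"], model.segments["LB2"]
        return s1.tissue_volume + s2.tissue_volume, s1.air_volume + s2.air_volume
    s = model.segments[seg]
    return s.tissue_volume, s.air_volume


def _anatomical(seg):
    return {"LB1", "LB2"} if seg == "LB1+2" else {seg}


def _lobe_sets(side):
    if side == "left":
        units = ["LB1", "LB2", "LB3", "LB1+2"]
    else:
        units = ["RB1", "RB2", "RB3"]
    sets = [(u,) for u in units]
    for a, b in combinations(units, 2):
        if _anatomical(a) & _anatomical(b):
            continue
        if {a, b} == {"LB1", "LB2"}:
            continue  # same tissue as the merged single, already present
        sets.append(tuple(sorted((a, b))))
    return sets


def oracle_enumerate(primary_side):
    sides = ["left", "right"] if primary_side == "both" else [primary_side]
    opts = []
    for side in sides:
        other = "right" if side == "left" else "left"
        for s1 in ("LB1", "LB2", "LB3", "LB1+2") if side == "left" else ("RB1", "RB2", "RB3"):
            for s2 in _lobe_sets(other):
                opts.append((side, s1, s2))
    return opts


def _lobe_volume(model, side, denominator):
    ids = ["LB1", "LB2", "LB3"] if side == "left" else ["RB1", "RB2", "RB3"]
    if side == "left" and denominator == "anatomical":
        ids += ["LB4", "LB5"]
    total = 0.0
    for s in ids:
        seg = model.segments[s]
        total += seg.tissue_volume + seg.air_volume
    return total


def oracle_plan(model, primary_side="both", cap=1700.0, hi_min=1.2,
                s1_win=(30.0, 70.0), s2_win=(40.0, 80.0), comb_win=(95.0, 130.0),
                equal_tol=2.0, tar_tol=0.30, target=110.0):
    """Return the oracle's chosen option key, or None when infeasible."""
    denominator = model.denominator
    survivors = []
    for side, s1, s2 in oracle_enumerate(primary_side):
        other = "right" if side == "left" else "left"
        t1, a1 = _volumes(model, s1)
        v1 = t1 + a1
        t2 = a2 = v2 = 0.0
        for seg in s2:
            ts, as_ = _volumes(model, seg)
            t2 += ts
            a2 += as_
            v2 += ts + as_
        f1 = 100.0 * v1 / _lobe_volume(model, side, denominator)
        f2 = 100.0 * v2 / _lobe_volume(model, other, denominator)
        if not (s1_win[0] <= f1 <= s1_win[1]):
            continue
        if not (s2_win[0] <= f2 <= s2_win[1]):
            continue
        if not (comb_win[0] <= f1 + f2 <= comb_win[1]):
            continue
        if v1 > cap or v2 > cap:
            continue
        ok = True
        for seg in (s1,) + s2:
            ts, as_ = _volumes(model, seg)
            lobe_side = "left" if seg.startswith("L") else "right"
            if model.lower_lobe_tar[lobe_side] / _tar(ts, as_) < hi_min:
                ok = False
        if not ok:
            continue
        ctar = _tar(t1 + t2, a1 + a2)
        survivors.append({"side": side, "s1": s1, "s2": s2, "frac": f1 + f2, "ctar": ctar})
    if not survivors:
        return None

    # Least-diseased dominance, per lobe, guarded against emptying the set.
    for lobe_side in ("left", "right"):
        ids = ["LB1", "LB2", "LB3"] if lobe_side == "left" else ["RB1", "RB2", "RB3"]
        tars = {s: _tar(model.segments[s].tissue_volume, model.segments[s].air_volume) for s in ids}
        top = max(tars, key=tars.get)
        unique = all(tars[top] - tars[s] > equal_tol for s in ids if s != top)
        if not unique:
            continue
        kept = []
        for o in survivors:
            treated = set()
            for seg in (o["s1"],) + o["s2"]:
                treated |= _anatomical(seg)
            if top not in treated:
                kept.append(o)
        if kept:
            survivors = kept

    best = min(o["ctar"] for o in survivors)
    tie = [o for o in survivors if o["ctar"] - best <= tar_tol]
    tie.sort(key=lambda o: (abs(o["frac"] - target), o["side"], o["s1"], o["s2"]))
    w = tie[0]
    return f"{w['side']}:{w['s1']}|{'&'.join(w['s2'])}"
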