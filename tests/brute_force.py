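"""Independent brute-force re-evaluation of the curtailment prescription.

Deliberately avoids the package's geometry and engine code: distances,
closing speeds, cylinder membership and order intervals are recomputed here
from first principles with plain ``math``, so the engine can be checked
against a second route.
"""

from __future__ import annotations

import math
from datetime import timedelta


def _velocity(track, i):
    recs = track.records
    if len(recs) == 1:
        return None
    j, k = max(i - 1, 0), min(i + 1, len(recs) - 1)
    dt = (recs[k].timestamp - recs[j].timestamp).total_seconds()
    if dt <= 0:
        return None
    return (
        (recs[k].x - recs[j].x) / dt,
        (recs[k].y - recs[j].y) / dt,
        (recs[k].z - recs[j].z) / dt,
    )


def qualifies(rec, vel, turbine, cfg) -> bool:
    """Re-statement of the rule: confidence > threshold and (inner cylinder,
    or outer cylinder with time-to-collision <= limit)."""
    if not rec.confidence > cfg.confidence_threshold:
        return False
    bx, by = turbine.base_position
    horiz = math.sqrt((rec.x - bx) ** 2 + (rec.y - by) ** 2)
    in_height = 0.0 <= rec.z <= cfg.height_cap_m
    if horiz <= cfg.inner_radius_m and in_height:
        return True
    if vel is None or horiz > cfg.outer_radius_m or not in_height:
        return False
    cx, cy, cz = bx, by, turbine.hub_height
    dx, dy, dz = cx - rec.x, cy - rec.y, cz - rec.z
    range_to_center = math.sqrt(dx * dx + dy * dy + dz * dz)
    dist = range_to_center - turbine.rotor_diameter / 2.0
    if dist <= 0:
        return True  # inside the RSZ: collision time zero
    if range_to_center == 0:
        return True
    closing = (vel[0] * dx + vel[1] * dy + vel[2] * dz) / range_to_center
    if closing <= 0:
        return False
    return dist / closing <= cfg.ttc_limit_s


def brute_force_orders(track, turbines, cfg):
    """Expected orders as (track_id, turbine_id, start, end) tuples: merge
    qualifying instants whose gaps do not exceed the release hold, then pad
    each run by the hold."""
    hold = timedelta(seconds=cfg.release_hold_s)
    out = []
    for turbine in turbines:
        instants = [
            rec.timestamp
            for i, rec in enumerate(track.records)
            if qualifies(rec, _velocity(track, i), turbine, cfg)
        ]
        if not instants:
            continue
        runs = [[instants[0], instants[0]]]
        for t in instants[1:]:
            if t - runs[-1][1] <= hold:
                runs[-1][1] = t
            else:
                runs.append([t, t])
        for start, last in runs:
            out.append((track.track_id, turbine.turbine_id, start, last + hold))
    return out
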