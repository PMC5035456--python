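"""Differential g-sphere: contrasting two recording situations.

Two programmes share a resting state but differ in the posture of their
active state (e.g. the same subject before/after an injury that changes
gait posture).  Differencing the two normalised g-spheres cancels the
shared behaviour and concentrates mass exactly where the programmes
disagree; the signed layer says which situation used each posture more.
"""

import numpy as np

from gsphere import (
    BehaviourProgramme, BehaviourState, bin_series, build_geodesic,
    difference, dynamic_component, normalize, normalize_to_sphere,
    simulate, smooth_static, vedba,
)

sphere = build_geodesic(3)


def run(active_pitch, seed):
    states = [
        BehaviourState("rest", pitch=-16, roll=18, dyn_amplitude=0.05,
                       dyn_freq_hz=2.0, noise_sd=0.02),
        BehaviourState("active", pitch=active_pitch, roll=18, dyn_amplitude=0.5,
                       dyn_freq_hz=2.0, noise_sd=0.02),
    ]
    prog = BehaviourProgramme(states=states, duration_s=300, rate_hz=40,
                              dwell_s=20, seed=seed)
    trace = simulate(prog)
    static = smooth_static(trace, 40)
    v = vedba(dynamic_component(trace, static))
    return normalize(bin_series(normalize_to_sphere(static), v, sphere), "global")


ga = run(active_pitch=44, seed=1)   # situation A: active posture pitched up 44
gb = run(active_pitch=20, seed=2)   # situation B: active posture pitched up 20

gd = difference(ga, gb)
print(f"total |difference| mass: {gd.counts.sum():.1f} percentage points")
print("facets holding the largest differences:")
for fid in np.argsort(-gd.counts)[:4]:
    sign = "A>B" if gd.signed_counts[fid] > 0 else "B>A"
    print(f"  facet {fid}: |diff| {gd.counts[fid]:5.2f} pp  ({sign})")
print("the shared resting facet nearly cancels; the two active postures "
      "appear as opposite-signed hotspots")
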