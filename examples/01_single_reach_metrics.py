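"""Metrics of a single smooth reach, checked against their closed forms.

Generates a noise-free 300 mm, 1 s minimum-jerk reach sampled at 200 Hz and
computes each metric directly from the wrist trajectory.  For this ideal
movement every value has an analytic expectation (printed alongside), which
is how the library's numerics are validated.
"""

import math

from armkin import (
    Path3D,
    ScalarProfile,
    SynthSpec,
    count_velocity_peaks,
    differentiate,
    generate_reach,
    hand_path_ratio,
    log_dimensionless_jerk,
    mean_velocity,
    movement_time,
    peak_velocity,
    sparc,
    speed_profile,
    split_segments,
    time_to_peak_velocity,
    velocity_ratio,
    zero_crossings_accel,
)

rec, truth = generate_reach(SynthSpec(amplitude=300.0, duration=1.0, rate=200.0))
seg = split_segments(rec)[0]
path = Path3D(times=rec.timestamps[seg.start : seg.stop], points=rec.positions["RWR"][seg.start : seg.stop])
speed = speed_profile(path)
tacc = differentiate(speed, 1)
interior = ScalarProfile(times=tacc.times[1:-1], values=tacc.values[1:-1])

rows = [
    ("movement time [s]", movement_time(seg), truth.movement_time),
    ("mean velocity [mm/s]", mean_velocity(speed), truth.mv),
    ("peak velocity [mm/s]", peak_velocity(speed), truth.pv),
    ("velocity ratio MV/PV", velocity_ratio(speed), 8 / 15),
    ("time to peak velocity [%]", time_to_peak_velocity(speed, seg), 50.0),
    ("velocity peaks (NPV)", count_velocity_peaks(speed), 1),
    ("accel zero crossings", zero_crossings_accel(interior), 1),
    ("log dimensionless jerk", log_dimensionless_jerk(path), -math.log(720)),
    ("spectral arc length", sparc(speed), None),
    ("hand path ratio", hand_path_ratio(path), 1.0),
]
print(f"{'metric':28s} {'computed':>12s} {'analytic':>12s}")
for name, got, want in rows:
    want_s = f"{want:12.4f}" if want is not None else "           -"
    print(f"{name:28s} {got:12.4f} {want_s}")
print(
    "\nA single ideal reach: one velocity peak at mid-movement, hand path"
    "\nratio 1 (perfectly straight), LDJ at the smoothness optimum -ln 720."
)
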