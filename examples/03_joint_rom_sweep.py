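"""Joint angles and range of motion from scripted sweeps.

Generates recordings in which the right elbow flexes 20°-110° and the right
shoulder elevates 0°-90° (sinusoidally, by forward kinematics), then recovers
the prescribed range of motion from the marker positions alone — the same
computation a clinician's goniometer approximates.
"""

from armkin import angle_series, generate_angle_sweep, rom_range

for joint, lo, hi in (("right_elbow", 20.0, 110.0), ("right_shoulder", 0.0, 90.0)):
    rec = generate_angle_sweep(joint, lo, hi, cycles=1, rate=100.0)
    rr = rom_range(angle_series(rec, joint))
    print(
        f"{joint:15s} prescribed {hi - lo:5.1f} deg  "
        f"recovered {rr.rom:6.2f} deg  (min {rr.min_angle:6.2f}, max {rr.max_angle:6.2f})"
    )
print("\nElbow angle: upper-arm vs forearm vector (0 deg = extended).")
print("Shoulder angle: upper-arm vs horizontal virtual-trunk direction.")
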