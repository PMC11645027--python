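"""Simulate one instrumented five-time sit-to-stand test and inspect it.

Builds a stage-1 participant, synthesises the trunk IMU signals at 100 Hz
and prints the ground-truth transition times alongside basic signal
statistics. The pitch angular-velocity trough depths are what the
segmenter later keys on.
"""

import numpy as np

import locomo as lm

profile = lm.ParticipantProfile("demo_000", "Stage1", "F", 74.0, glfs_score=11)
recording = lm.simulate_ftsts(profile, n_cycles=5, sample_rate_hz=100.0, seed=42)

print(f"participant {profile.participant_id}: group={profile.group}, GLFS-25={profile.glfs_score}")
print(f"recording: {len(recording)} samples at {recording.sample_rate_hz:.0f} Hz "
      f"({recording.duration_s:.1f} s)")
print("ground-truth transitions (seat-off = rising, seat-on = sitting down):")
for kind, t in recording.ground_truth_events:
    print(f"  {kind:9s} at {t:6.2f} s")

pitch = recording.pitch_velocity
print(f"pitch angular velocity: min {pitch.min():.1f} deg/s "
      f"(the transition troughs), rms {np.sqrt(np.mean(pitch**2)):.1f} deg/s")
ap = recording.accel[:, 1]
print(f"AP acceleration: peak |a| {np.abs(ap).max():.2f} m/s^2 around each transition")
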