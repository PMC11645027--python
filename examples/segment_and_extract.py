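"""Preprocess, segment and feature-extract one sit-to-stand recording.

Runs the conditioning chain (zero-center, resample to 50 Hz, 5 Hz
Butterworth), detects the transition troughs in the pitch channel,
builds SiSt/StSi/SSS/FTSTS windows and prints a few of the 144 metrics.
"""

import locomo as lm

profile = lm.ParticipantProfile("demo_001", "NonLS", "M", 68.0, glfs_score=3)
raw = lm.simulate_ftsts(profile, seed=7)

pre = lm.preprocess_recording(raw)
print(f"preprocessed: {raw.sample_rate_hz:.0f} Hz -> {pre.sample_rate_hz:.0f} Hz, "
      f"{len(raw)} -> {len(pre)} samples")

segments = lm.segment_recording(pre)
kinds = [s.kind for s in segments]
print(f"segments: {kinds.count('SiSt')} SiSt, {kinds.count('StSi')} StSi, "
      f"{kinds.count('SSS')} SSS, 1 FTSTS")

fv = lm.build_feature_vector(pre, segments)
print(f"feature vector: {len(fv)} primary metrics")
for key in ("FTSTS_RES_duration", "SiSt_RES_duration", "SiSt_AP_rms",
            "SiSt_AP_jerk", "SSS_RES_sef95"):
    print(f"  {key:22s} = {fv.values[key]:.4f}")
print("durations are seconds, rms in m/s^2, jerk in m^2/s^5, SEF in Hz;")
print("slower, less powerful transitions shift durations up and spectral edges down.")
cv = fv.cv_supplement["cv_SiSt_RES_duration"]
print(f"repetition-to-repetition variability: CV of SiSt duration = {cv:.3f}")
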