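"""From marker trajectories to normalized expansion scores.

Computes each trial's mean segment lengths (mm), then expresses every
performance trial as a percent change from the same subject's neutral
recitation — removing face size and speech articulation in one step.
"""

from pathlib import Path

from facekin import SimConfig, simulate_cohort
from facekin.mocap import read_trial
from facekin.normalize import normalize_cohort, screen_outliers
from facekin.segments import extract_trial_features, features_to_frame

config = SimConfig(n_subjects=3, duration_s=5.0, seed=2, jitter_sd_mm=0.3)
cohort = simulate_cohort(config, Path("example_out/features"))

features = features_to_frame([
    extract_trial_features(read_trial(row["path"]),
                           subject_id=row["subject_id"],
                           condition=row["condition"])
    for _, row in cohort.manifest.iterrows()
])
print("Raw mean segment lengths (mm), first subject:")
cols = ["condition", "brow", "eyebrow", "lips", "jaw"]
print(features[features["subject_id"] == "S01"][cols].head(5)
      .to_string(index=False, float_format="%.2f"))

normalized = normalize_cohort(features)
print("\nPercent change vs the neutral baseline (same subject):")
print(normalized[normalized["subject_id"] == "S01"][cols].head(5)
      .to_string(index=False, float_format="%+.2f"))
print("\nPositive = expansion relative to neutral speech. Subjects with "
      "faces of different sizes now share one scale.")

flags = screen_outliers(normalized)
print(f"\noutlier screen (|robust z| > 4): {len(flags)} flags")
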