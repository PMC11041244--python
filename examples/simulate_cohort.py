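"""Generate a small synthetic cohort to disk and inspect its ground truth.

Writes one pen trace and one accelerometer stream per participant x task x
condition, plus a manifest and the generating parameters (for recovery
tests).  The default condition effects are 1.0, embedding the null: the
outcome-generating distribution is identical across vibration conditions.
"""

import tempfile
from pathlib import Path

import pandas as pd

from tremorkit import synthetic_data as sd

spec = sd.CohortSpec(
    n_participants=3,
    tasks=(sd.TaskSpec("spiral"), sd.TaskSpec("handwriting")),
    seed=11,
)
out = Path(tempfile.mkdtemp()) / "cohort"
manifest = sd.generate_cohort(spec, out)

print(f"wrote {len(manifest)} repetitions (3 participants x 2 tasks x 3 conditions) to {out}")
print(manifest.head(4).to_string(index=False))

truth = pd.read_csv(out / "ground_truth.csv")
print("\nground-truth tremor amplitude (px) by condition:")
print(truth.groupby("condition")["amplitude_px"].mean().round(2).to_string())
print("\nWith all condition effects at 1.0 the mean amplitudes differ only by")
print("sampling noise - the basis for the type-I-error calibration tests.")
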