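"""Build model-ready arrays from raw record and deployment tables.

Writes a simulated survey to CSV (the same schemas field data arrives in),
then ingests it: species filtering, effort matrix, detection history.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from occomm import (
    build_detection_history,
    build_effort,
    default_design,
    default_hyper,
    filter_species,
    simulate_survey,
    simulate_truth,
)
from occomm.synthetic import write_survey_csvs

truth = simulate_truth(default_hyper(), 25, seed=2)
design = default_design(seed=2)
sim = simulate_survey(truth, design, seed=2)

workdir = Path(tempfile.mkdtemp())
paths = write_survey_csvs(sim, workdir)
records = pd.read_csv(paths["records"])
stations = pd.read_csv(paths["stations"])
functionality = pd.read_csv(paths["functionality"])

# Species with <5 independent records (30-min interval) are dropped, as are
# taxa on the exclusion list.
filtered, report = filter_species(records, min_detections=5)
print(f"retained {report['retained'].sum()} of {len(report)} species")
print(report.head(5).to_string(index=False))

effort = build_effort(functionality, stations, occasion_length=5)
detections = build_detection_history(filtered, stations, effort, occasion_length=5)
print(f"\ndetection history: {dict(detections.sizes)}")
print(f"total functional camera-days: {int(effort.sum())}")
print(f"naive occupancy (any detection) for {detections.species.values[0]}: "
      f"{float((np.nan_to_num(detections[0].values) == 1).any(axis=1).mean()):.2f}")
# Naive occupancy underestimates true occupancy because detection is
# imperfect — the gap is what the occupancy model corrects.
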