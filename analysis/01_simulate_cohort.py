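"""Simulate the study cohort: 120 subjects (33 FEP / 22 BD / 13 SA / 13 CS /
39 HC), one 15-frame time-lapse each with three niacin patches (0.1, 0.01,
0.001 M) on synthetic forearm skin.

Writes the cohort configuration and metadata under results/, and one
example subject's frames (PNG) under scratch/ for visual inspection.
Frames are rendered at 160x200 px (20-px patches) to keep the full-cohort
analysis fast; the geometry is configurable.
"""

from pathlib import Path

from skinrems.config import CohortConfig, KernelParams, PatchLayout, save_config
from skinrems.io import write_frames, write_metadata_csv
from skinrems.synthetic import generate_cohort, metadata_frame

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 20260921

ANALYSIS_CONFIG = CohortConfig(
    layout=PatchLayout(frame_shape=(160, 200), patch_size=20, control_size=30),
    kernel=KernelParams(peak_time=240.0),
    seed=SEED,
)


def main():
    RESULTS.mkdir(exist_ok=True)
    save_config(ANALYSIS_CONFIG, RESULTS / "analysis_config.yaml")
    metadata, sequences, truths = generate_cohort(ANALYSIS_CONFIG)
    meta_df = metadata_frame(metadata)
    write_metadata_csv(meta_df, RESULTS / "metadata.csv")

    example = sequences[0]
    write_frames(example, SCRATCH / "example_frames" / example.subject_id)

    print(f"simulated {len(metadata)} subjects, {len(sequences)} sequences")
    print(meta_df["group"].value_counts().to_string())
    print(f"frames per sequence: {len(example)}")
    print(f"metadata -> {RESULTS / 'metadata.csv'}")
    print(f"example frames -> {SCRATCH / 'example_frames' / example.subject_id}")


if __name__ == "__main__":
    main()
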