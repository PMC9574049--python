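"""The whole pipeline on a reduced synthetic cohort, with reports on disk.

Simulates a cohort, runs preprocessing + stability ICA + SMN identification
+ peak extraction for every run, and writes ICC and distance reports in the
layout of published reliability tables (raw negative ICCs shown as "< 0",
unidentified runs as "-"). Takes a couple of minutes on one CPU.
"""

import warnings
from pathlib import Path

from smnpeak import CohortConfig, PipelineConfig, REDUCED_GRID, run_pipeline

warnings.filterwarnings("ignore", category=RuntimeWarning)

cohort = CohortConfig(
    n_subjects=4, visits=(("V1", "scannerA"), ("V2", "scannerA")),
    conditions=("EO",), n_volumes=80, grid=REDUCED_GRID,
    sigma_between_mm=8.0, sigma_within_mm=3.0, noise_sd=0.2,
    scanner_noise_scale=(("scannerA", 1.0),), seed=5)
config = PipelineConfig(
    out_dir=Path("example_output/pipeline"), cohort=cohort,
    n_components_settings=(8,), n_runs_icasso=5,
    visit_pairs=(("V1", "V2"),), seed=1, ica_max_iter=300)

result = run_pipeline(config)
print(result["ledger"].to_string(index=False))
for icc in result["icc_results"]:
    print(f"\n{icc.condition} {icc.side} {icc.visit_pair}: per-axis raw ICC "
          f"({icc.icc_x:.2f}, {icc.icc_y:.2f}, {icc.icc_z:.2f}) "
          f"-> averaged {icc.icc_avg:.2f} over n={icc.n_subjects_used}")
print(f"\nreports in {result['report_dir']}")
# The ledger shows one row per decomposition with its status; the averaged
# ICC per side summarizes how reproducible the extracted peak location is
# across the two simulated visits.
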