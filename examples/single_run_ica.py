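"""One run through the analysis chain: preprocess -> ICA -> identify -> peak.

Simulates a single 8-minute-style run, discards the first 10 volumes,
smooths at 6 mm FWHM, decomposes it with stability-selected Infomax ICA,
picks the SMN component by Dice overlap, and extracts the left/right peaks.
"""

import warnings

import numpy as np

from smnpeak import (CohortConfig, REDUCED_GRID, brain_mask, default_smn_mask,
                     discard_initial_volumes, extract_peak, icasso_decompose,
                     identify_smn, simulate_run, smooth_gaussian, zscore_align)

warnings.filterwarnings("ignore", category=RuntimeWarning)

config = CohortConfig(n_subjects=1, visits=(("V1", "scannerA"),),
                      conditions=("EO",), n_volumes=80, grid=REDUCED_GRID,
                      sigma_between_mm=4.0, sigma_within_mm=2.0,
                      noise_sd=0.2, seed=7)
vol, truth = simulate_run(config, 0, "V1", "EO")
vol = smooth_gaussian(discard_initial_volumes(vol, 10), fwhm_mm=6.0)

bmask = brain_mask(config.grid)
smn_mask = default_smn_mask(config.grid)
decomp = zscore_align(icasso_decompose(vol, bmask, n_components=8,
                                       n_runs=5, seed=1, max_iter=300))
selection = identify_smn(decomp, smn_mask)
print(f"SMN identification: mode={selection.mode}, "
      f"Dice top-1 = {selection.dice_top1:.3f}")

for side in ("left", "right"):
    rec = extract_peak(selection, decomp, smn_mask, side, subject=0,
                       visit="V1", condition="EO")
    err = np.linalg.norm(np.asarray(rec.coord_mm)
                         - truth["smn_peak_mm"][side])
    print(f"{side:>5} peak at {rec.coord_mm} mm (z = {rec.peak_z:.2f}), "
          f"{err:.1f} mm from the simulated truth")
# The peak coordinates are the candidate stimulation target; the error in mm
# against the generator's ground truth shows how well one run localizes it.
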