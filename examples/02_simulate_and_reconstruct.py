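"""Simulate one PET acquisition and reconstruct it with and without PRC.

Builds a small digital patient with a single hot soft-tissue lesion, blurs
the activity with the Ga-68 range kernel, projects it to a Poisson-noisy
sinogram, and reconstructs two BSREM images: one with the kernel inside the
forward/backward model (positron-range corrected, PRC) and one without.
The PRC image recovers a higher lesion SUVmax because the reconstruction
deconvolves the range blur.
"""

import numpy as np

from garange import (CohortConfig, LesionPlanEntry, ReconParams, SinogramGeometry,
                     SystemModel, VoxelGrid, build_patient, make_kernel,
                     reconstruct, simulate_acquisition)

grid = VoxelGrid((48, 48, 8))
config = CohortConfig(grid=grid,
                      lesion_plan=(LesionPlanEntry("soft", volume=0.8, uptake=12.0),))
patient = build_patient(config, seed=7)
print(f"patient: {patient.meta.weight:.0f} kg, "
      f"{patient.meta.injected_activity:.0f} MBq injected")

kernel = make_kernel("Ga-68", grid.spacing, n_samples=200_000, seed=1)
system = SystemModel(geometry=SinogramGeometry(24, 48, grid.spacing[0], 8))
sino = simulate_acquisition(patient, system, kernel, seed=3)
print(f"sinogram: {sino.values.shape} bins, {sino.values.sum():.0f} counts")

lesion = patient.labels >= 10
for label, prc in (("non-PRC", None), ("PRC", kernel)):
    params = ReconParams(beta=0.05, n_iterations=10, n_subsets=4, prc_kernel=prc)
    res = reconstruct(sino, patient, system, params)
    print(f"{label:8s} lesion SUVmax = {res.image[lesion].max():.2f}")

print("\nThe PRC arm systematically recovers a higher SUVmax: the in-loop "
      "kernel restores contrast the positron range smeared out (noisy "
      "deconvolution can overshoot the true uptake, which is why the study "
      "design compares the two arms at matched noise rather than against "
      "ground truth).")
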