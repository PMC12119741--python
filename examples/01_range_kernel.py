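"""Generate the Ga-68 positron-range kernel and inspect its physics.

Samples beta+ energies from the allowed Fermi spectrum, transports them to
annihilation displacements in water, and voxelizes the kernel at the clinical
grid spacing.  The printed mean energy (~844 keV) and mean 3D displacement
(~2.2 mm) are the physical reason Ga-68 PET images are blurrier than F-18:
the kernel quantifies how far activity "leaks" from its emission voxel.
"""

import numpy as np

from garange import default_spectrum, make_kernel, sample_energies

for nuclide in ("Ga-68", "F-18"):
    spectrum = default_spectrum(nuclide)
    energies = sample_energies(spectrum, 200_000, seed=1)
    kernel = make_kernel(nuclide, spacing=(2.73, 2.73, 2.80),
                         n_samples=200_000, seed=1)
    center = kernel.values[tuple(s // 2 for s in kernel.values.shape)]
    print(f"{nuclide}: mean beta+ energy {energies.mean():7.1f} keV | "
          f"mean annihilation displacement {kernel.mean_range:.2f} mm | "
          f"kernel mass in center voxel {100 * center:.1f}%")

print("\nA smaller center-voxel mass means more range blur to correct: "
      "the Ga-68 kernel spreads activity well beyond its emission voxel, "
      "the F-18 kernel barely does.")
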