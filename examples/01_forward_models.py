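"""Spherical forward models: shell cascade, EEG/MEG leadfields, sanity checks.

Builds the reference 6-shell conductor, an 80-channel EEG cap and a
273-channel axial-gradiometer helmet, computes leadfields for one cortical
position, and prints the two physical invariants that anchor the model:
common-average-referenced EEG gains sum to zero over electrodes, and a
radial dipole is magnetically silent in a spherical conductor.
"""
import numpy as np

from beamcascade import (eeg_sphere_leadfield, make_eeg_sensors, make_meg_sensors,
                         make_shell_model, meg_sphere_leadfield,
                         reference_orientations, CASCADE_LEVELS)

for level in CASCADE_LEVELS:
    m = make_shell_model(level)
    print(f"{level:>9}: radii {m.radii} mm, sigma {m.conductivities} S/m")

shells = make_shell_model("reference")
eeg = make_eeg_sensors(80, shells)
meg = make_meg_sensors(273)
node = np.array([30.0, -20.0, 55.0])  # a cortical position, mm

g_eeg = eeg_sphere_leadfield(shells, eeg, node)
print(f"\nEEG gain at {node} mm: shape {g_eeg.shape}, "
      f"|column sums| <= {np.max(np.abs(g_eeg.sum(axis=0))):.2e}  "
      "(zero by common average reference)")

g_meg = meg_sphere_leadfield(meg, node)
radial = node / np.linalg.norm(node)
print(f"MEG gain: shape {g_meg.shape}, |radial response|/|gain| = "
      f"{np.linalg.norm(g_meg @ radial) / np.linalg.norm(g_meg):.2e}  "
      "(radial dipoles are silent)")

quasi_radial, quasi_tangential = reference_orientations(g_meg)
print(f"quasi-radial ori {np.round(quasi_radial, 3)} "
      f"(|dot with radial| = {abs(quasi_radial @ radial):.6f}), "
      f"quasi-tangential ori {np.round(quasi_tangential, 3)}")
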