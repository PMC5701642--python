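"""Beamformer scan and localization of one simulated spike source.

Simulates a quasi-tangential 100 nAm spike source (low noise), scans a
600-node source space with the three constrained LCMV filters and localizes
by output variance and by excess kurtosis.  The expected localization error
is the source-space offset: every reference source sits 0.5–0.6 mm from its
nearest grid node, so ~0.55 mm is a perfect (grid-floor) recovery.
"""
import numpy as np

from beamcascade import (add_white_noise, assemble_measurement, build_source_space,
                         common_average_reference, compute_leadfields,
                         demean_channels, localize, make_eeg_sensors,
                         make_meg_sensors, make_shell_model, make_spike_waveform,
                         make_reference_sources, reference_orientations, scan,
                         CONSTRAINTS, NOISE_VARIANCES)

shells = make_shell_model("reference")
eeg = make_eeg_sensors(80, shells)
refs = make_reference_sources(60, 70.0, seed=1)
space = build_source_space(600, shells, refs, seed=2, cortex_radius=70.0)
lead = compute_leadfields(shells, eeg, space.node_positions)

src = 0
_, tangential = reference_orientations(
    compute_leadfields(shells, make_meg_sensors(273), refs[src:src + 1]).node_gain(0))
gain = compute_leadfields(shells, eeg, refs[src:src + 1]).node_gain(0)

wf = make_spike_waveform()
meas = assemble_measurement(gain @ tangential, wf, [1200, 3120], duration_s=4.0,
                            rate=1200.0, amplitude_nam=100.0, modality="eeg")
meas = add_white_noise(meas, NOISE_VARIANCES["eeg"][0], seed=3)
meas = demean_channels(common_average_reference(meas))

print(f"true source at {np.round(refs[src], 1)} mm, orientation "
      f"{np.round(tangential, 3)}")
for constraint in CONSTRAINTS:
    outs = scan(space, lead, meas, constraint, loading=0.03)
    for criterion in ("variance", "kurtosis"):
        res = localize(outs, criterion, true_position=refs[src])
        print(f"  {constraint:>16} / {criterion:<8}: node {res.estimated_node:4d} "
              f"at {np.round(res.estimated_position, 1)}, "
              f"error {res.error_mm:.2f} mm")
print("errors of ~0.55 mm are the grid floor imposed by the offset rule.")
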