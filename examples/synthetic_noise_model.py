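"""The synthetic-data noise model and its analytic moments.

Structure-factor amplitudes receive noise F + sqrt(F) * eps * d * 0.5 with
eps standard normal; at F = 100 and d = 2.0 A the amplitudes keep their
mean and gain a standard deviation of sqrt(100) * 2.0 * 0.5 = 10.
Coordinates are shaken with an RMS of 0.2 * d per atom.
"""

import numpy as np

import mcbuild as mc

n = 100_000
sf = mc.StructureFactors(
    hkl=np.zeros((n, 3), dtype=int),
    amplitude=np.full(n, 100.0),
    phase=np.zeros(n),
    d_min=2.0,
    cell=np.array([50.0, 50.0, 50.0]),
    grid_shape=(2, 2, 2),
)
noisy = mc.add_structure_factor_noise(sf, resolution=2.0, noise_scale=0.5, seed=0)
print(f"amplitude mean {noisy.amplitude.mean():.2f} (expect 100.00)")
print(f"amplitude sd   {noisy.amplitude.std():.2f} (expect 10.00)")

peptide = mc.build_ideal_peptide(["ALA"] * 20)
before = np.array([a.pos for a in peptide.all_atoms()])
shaken = mc.shake_coordinates(peptide, rmse=0.2 * 2.0, seed=0)
after = np.array([a.pos for a in shaken.all_atoms()])
rms = float(np.sqrt(np.mean(np.sum((after - before) ** 2, axis=1))))
print(f"shake RMS      {rms:.3f} A (target 0.2 * 2.0 = 0.400)")
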