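"""Pore-size statistics and the elementary physical formulas.

Pore diameters extracted from micrographs are binned into fixed 10-um
bins (0-80 um) and the histogram is fitted with a scaled LogNormal
density.  The script also shows the density, Young's modulus and
PVA-weight recipe helpers.
"""

import numpy as np

from pahydro import bin_pores, density, elastic_modulus, fit_lognormal, pva_weight

rng = np.random.default_rng(7)
diameters = rng.lognormal(mean=np.log(12.0), sigma=0.55, size=8000)  # um

hist = bin_pores(diameters)
print("bin edges (um):", hist.bin_edges.astype(int).tolist())
print("counts        :", hist.counts.astype(int).tolist())

fit = fit_lognormal(hist)
print(f"LogNormal fit: median diameter {fit.median_diameter:.1f} um, "
      f"sigma = {fit.sigma:.3f}, R^2 = {fit.r_squared:.4f}")

print(f"density of a 1.05 g sample displacing 1.0 cm^3: "
      f"{density(1.05, 1.0):.2f} g/cm^3")
print(f"Young's modulus at 10 kPa stress, 10% strain: "
      f"{elastic_modulus(10.0, 0.10):.0f} kPa")
print(f"PVA powder for 7% in 150 mL of water: {pva_weight(7.0, 150.0):.1f} (recipe units)")
# Most pores fall in the 0-20 um bins; higher PVA content shifts the
# distribution toward smaller pores and higher density.
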