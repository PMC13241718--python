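"""FWHM reference segmentation and scar-mass quantification.

On a noise-free phantom the half-peak threshold recovers the scar wedge
exactly; the mass from voxel geometry (density 1.05 g/cm^3) matches the
analytic wedge formula.
"""

import numpy as np

from scarseg.phantom import PhantomSpec, analytic_scar_area_mm2, generate_slice
from scarseg.quantify import MYOCARDIAL_DENSITY_G_PER_CM3, dsc, fwhm_segment, scar_mass

spec = PhantomSpec(grid_size=176, pixel_spacing_mm=0.8, noise_sd=0.0, bias_amplitude=0.0)
rec = generate_slice(spec)

# operator ROI: a 3x3 patch at the scar centroid
roi = np.zeros_like(rec.scar_mask)
r, c = np.argwhere(rec.scar_mask).mean(axis=0).astype(int)
roi[r - 1 : r + 2, c - 1 : c + 2] = True
roi &= rec.scar_mask

fwhm = fwhm_segment(rec.image, rec.myo_mask, roi)
print(f"FWHM vs ground truth DSC: {dsc(fwhm, rec.scar_mask):.3f}")

measured = scar_mass(rec.scar_mask, rec.geometry)
analytic = (analytic_scar_area_mm2(spec) * spec.slice_thickness_mm
            * MYOCARDIAL_DENSITY_G_PER_CM3 * 1e-3)
print(f"scar mass: measured {measured:.3f} g, analytic {analytic:.3f} g "
      f"({100 * abs(measured - analytic) / analytic:.2f}% apart)")
# DSC 1.000 confirms the half-peak rule separates the two tissue levels;
# the sub-percent mass gap is pure rasterization error.
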