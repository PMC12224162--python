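"""Five-point sucrose calibration with detection limits.

Single-standard runs at 5-25 mM are decomposed, the sucrose elution curve is
integrated over its window, and the areas are regressed on concentration.
LOD and LOQ follow the residual-standard-error convention (3x and 10x
se/slope), reported in both molar and mass units.
"""

from hilicraman import presets
from hilicraman.decompose import ComponentLibrary, svd_factor, target_rotation
from hilicraman.quantify import integrate_window, linear_calibration

points = []
for j, level in enumerate((5.0, 10.0, 15.0, 20.0, 25.0)):
    chrom, _ = presets.single_sugar_run("Suc", level, seed=800 + j)
    spectra = presets.model_spectra(chrom.waxis)
    lib = ComponentLibrary([
        spectra["Suc"], spectra["ACN"], spectra["H2O"], spectra["ACN-shift"],
        spectra["baseline"], spectra["drift"],
    ])
    D = target_rotation(svd_factor(chrom), 8, lib)
    area = integrate_window(D.taxis.values, D.curve("Suc"),
                            presets.INTEGRATION_WINDOWS["Suc"])
    points.append((level, area))
    print(f"  {level:5.1f} mM -> area {area:.4f} a.u.*min")

cal = linear_calibration(points, mw=presets.MOLECULAR_WEIGHTS["Suc"])
print(f"slope {cal.slope:.5f} a.u.*min/mM, intercept {cal.intercept:.5f}, "
      f"R^2 = {cal.r2:.6f}")
print(f"LOD = {cal.lod_molar:.4f} mM ({cal.lod_mass:.1f} ug/mL), "
      f"LOQ = {cal.loq_molar:.4f} mM ({cal.loq_mass:.1f} ug/mL)")
print(f"LOQ/LOD = {cal.loq_molar / cal.lod_molar:.4f} (10/3 by construction)")
print("-> the response is linear over the 5-fold range; the detection limits")
print("   scale with the scatter of the calibration points around the line.")
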