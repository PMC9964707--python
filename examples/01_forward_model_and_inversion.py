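"""Forward-simulate a diffuse-reflectance pair and invert it back.

Builds two tissue states a few days apart, simulates the detected spectra
with the modified Beer-Lambert forward model, and recovers the planted
hemoglobin concentration changes from the differential optical density at
740/840 nm.  Noise-free, the recovery is exact: CW-NIRS cannot see the
geometry constant G, but G cancels in the difference.
"""

from cwnirs import (
    AcquisitionMeta,
    ConcentrationState,
    ProbeGeometry,
    compute_od,
    delta_od,
    load_extinction_table,
    simulate_spectrum,
    solve_concentration_changes,
)
from cwnirs.synthetic import default_reference, default_simulation_geometry

chrom = load_extinction_table()
sim_geom = default_simulation_geometry()          # DPF over the full grid
geom = ProbeGeometry()                            # analysis: DPF at 740/840 only
ref = default_reference()

day0 = ConcentrationState(hbo2=0.070, hb=0.030)   # mM, StO2 = 70%
day3 = ConcentrationState(hbo2=0.075, hb=0.027)   # planted change (+5, -3) uM

geom_g = ProbeGeometry(d_mm=8.0, dpf=sim_geom.dpf, g=1.3)
spec0 = simulate_spectrum(day0, geom_g, chrom, ref, meta=AcquisitionMeta("r1", "Mg", "left", 0))
spec3 = simulate_spectrum(day3, geom_g, chrom, ref, meta=AcquisitionMeta("r1", "Mg", "left", 3))

dod = delta_od(compute_od(spec0, ref), compute_od(spec3, ref))
dc = solve_concentration_changes(dod, geom, chrom)

print(f"planted   dHbO2 = +0.005000 mM,  dHb = -0.003000 mM")
print(f"recovered dHbO2 = {dc.d_hbo2:+.6f} mM,  dHb = {dc.d_hb:+.6f} mM")
print(f"condition number of the 2x2 extinction system: {dc.condition_number:.1f}")
# The recovered changes match the planted ones to machine precision even
# though the simulation included an arbitrary geometry offset G = 1.3.
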