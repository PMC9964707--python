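"""Recover a subject's StO2 time course from noisy longitudinal spectra.

Simulates one Mg-implanted subject over the six study days with 1%
instrument noise, then runs the differential MBLL analysis against the
pre-surgery day-0 acquisition and prints recovered vs true StO2.  The
recovered values are semi-quantitative: they assume the day-0 state was
70% saturation with 0.1 mM total hemoglobin.
"""

import numpy as np

from cwnirs import (
    AcquisitionMeta,
    ConcentrationState,
    ProbeGeometry,
    load_extinction_table,
    simulate_spectrum,
    sto2_timeseries,
)
from cwnirs.synthetic import StudyRecord, default_reference, default_simulation_geometry

chrom = load_extinction_table()
sim_geom = default_simulation_geometry()
ref = default_reference()
rng = np.random.default_rng(0)

# planted trajectory: post-surgical dip recovering by day 45
true_sto2 = {0: 0.70, 1: 0.60, 3: 0.62, 7: 0.66, 14: 0.68, 45: 0.70}
thb = 0.1  # mM

geom_g = ProbeGeometry(d_mm=8.0, dpf=sim_geom.dpf, g=rng.uniform(0.5, 1.5))
records = []
for day, s in true_sto2.items():
    state = ConcentrationState(hbo2=s * thb, hb=(1 - s) * thb)
    spec = simulate_spectrum(state, geom_g, chrom, ref, noise_rel=0.01, rng=rng,
                             meta=AcquisitionMeta("Mg01", "Mg", "left", day))
    records.append(StudyRecord(spectrum=spec, reference=ref, truth=state))

series = sto2_timeseries(records, ProbeGeometry(), chrom)

print("day   true StO2   recovered StO2   error")
for est in series:
    truth = 100 * true_sto2[est.timepoint]
    print(f"{est.timepoint:3d}   {truth:7.1f}%   {est.sto2_percent:11.1f}%   "
          f"{est.sto2_percent - truth:+5.2f} pp")
# Typical errors at 1% noise are around one percentage point; day 0 is the
# differential anchor and maps to the assumed baseline exactly.
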