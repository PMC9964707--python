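# Differential pathlength factors (dimensionless) for an 8 mm source-detector
# separation probe, literature values at the two analysis wavelengths.
# Columns: wavelength_nm  dpf
wavelength_nm	dpf
740	3.50
840	3.01
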