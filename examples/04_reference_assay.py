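"""Compute reference chlorophyll contents from spectrophotometer
absorbances: the destructive assay that grounds the calibration.
"""

from chloroleaf import AbsorbanceRecord, arnon_concentrations, reference_from_absorbances

# extract of 0.03 g of leaf in 5 mL of 80% acetone, read in a 1 cm cuvette
record = AbsorbanceRecord(a645=0.3, a663=0.8, leaf_mass=0.03)

ca, cb, ct = arnon_concentrations(record.a645, record.a663)
print(f"extract concentrations: Ca = {ca:.3f}, Cb = {cb:.3f}, Ct = {ct:.3f} mg/L")

ref = reference_from_absorbances(record)
print(f"per-mass contents: CL-a = {ref.cla:.3f}, CL-b = {ref.clb:.3f}, "
      f"TCL = {ref.tcl:.3f} mg/g")
# The a/b ratio near 3 is typical of a sun-adapted leaf; these mg/g values
# are what the detector's color-feature models are calibrated against.
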