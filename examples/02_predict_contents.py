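"""Predict chlorophyll contents for a leaf reading with the calibrated
production models, including the plausibility guard.
"""

from chloroleaf import SensorReading, extract_features, predict_all

# wheat leaf, replicate mean
leaf = extract_features(SensorReading(27.9, 27.0, 18.8, 80.9))
est = predict_all(leaf)
print("wheat leaf estimate (mg/g fresh leaf):")
print(f"  CL-a = {est.cla:.3f}, CL-b = {est.clb:.3f}, TCL = {est.tcl:.3f}  [{est.status}]")
# ~2.1 mg/g chlorophyll-a is mid-range for field wheat (observed 1.05-3.44).

# a defective measurement (sensor saw almost nothing) trips the guard
bad = extract_features(SensorReading(0.1, 0.1, 0.1, 1.0))
print(f"defective reading -> status: {predict_all(bad).status}")
# The device would display "detection error" instead of a number.
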