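"""Turn one raw RGBC sensor reading into the 20 color features.

The reading below is the replicate-mean of a real wheat leaf measured
10 times on the same point (channels in counts/uW/cm2).
"""

from chloroleaf import SensorReading, extract_features

reading = SensorReading(r_raw=27.9, g_raw=27.0, b_raw=18.8, c_raw=80.9)
features = extract_features(reading)

print("normalized indices (0-255 scale, illumination cancelled):")
print(f"  R = {features.r:.2f}, G = {features.g:.2f}, B = {features.b:.2f}")
print("HSV (hue in degrees, saturation/value in [0,1]):")
print(f"  H = {features.h:.2f}, S = {features.s:.4f}, V = {features.v:.4f}")
print(f"example combination index R/B = {features.r_over_b:.4f}")
print(f"total features: {len(features)}")
# A healthy green leaf sits around H ~ 54 deg (yellow-green); the five
# features B, B', H, S, V are the ones the content models consume.
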