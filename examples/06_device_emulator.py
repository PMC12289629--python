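"""Walk the handheld device's firmware state machine: power on, measure
a leaf, flip through the three result pages, transmit.
"""

from chloroleaf import DeviceEmulator, SensorReading

leaf = SensorReading(27.9, 27.0, 18.8, 80.9)
device = DeviceEmulator(transmit_sink=lambda est: print(f"  [bluetooth] {est}"))

script = ["power_on", "tick", "press_detect", ("reading", leaf),
          "press_flip", "press_flip", "press_transmit"]
for item in script:
    event, reading = item if isinstance(item, tuple) else (item, None)
    device.send(event, reading=reading)
    print(f"{event:>14s} -> {device.state.state:<11s} display: {device.display()}")

print("states visited:", " -> ".join(device.history))
# The two flips move the display from CL-a to TCL; transmission emulates
# the Bluetooth push of the current estimate to a phone.
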