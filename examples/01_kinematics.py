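"""Dual-axis turntable kinematics: what stimulus does a setting deliver?

For each main-axis velocity of the standard protocol grid this prints the
exact tilt angle of the gravito-inertial vector (arctan(w^2 r / g) at
r = 17 cm), the round protocol label, and the GIA magnitude; eccentric-axis
velocities map to otolith modulation frequencies at |V_E|/360.
"""

from povar import (StimulusProfile, equivalent_tilt_angle, gia_magnitude,
                   modulation_frequency, nominal_tilt_angle)

print("main axis   exact tilt   label   |GIA|")
for v in (186, 264, 336, 408):
    profile = StimulusProfile(paradigm="pOVAR", main_axis_velocity=v,
                              eccentric_axis_velocity=72)
    print(f"{v:7.0f}deg/s  {equivalent_tilt_angle(v, 0.17):8.2f}deg"
          f"  {nominal_tilt_angle(v, 0.17):4.0f}deg  {gia_magnitude(profile):.3f} m/s^2")

print("\neccentric axis -> modulation frequency")
for v in (36, 72, 108, 144):
    print(f"{v:7.0f} deg/s -> {modulation_frequency(v):.1f} Hz")
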