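"""Drive a barrier crossing with ratchet-and-pawl dynamics.

A 15 kBT barrier separates two wells 17 A apart.  Unbiased Langevin dynamics
stays trapped on this timescale; the one-sided harmonic pawl
(k = 5 kJ/mol/A^2, the equivalent of 500 kJ/mol/nm^2) rectifies thermal
fluctuations and carries every run across.
"""

from metacv import KB, DoubleWell, LangevinParams, RatchetBias, integrate

pot = DoubleWell(barrier=15 * KB * 300.0, separation=17.0)
left, right = pot.well_positions()
print(f"wells at {left:.1f} and {right:.1f} A; barrier {pot.energy(0.0) - pot.energy(left):.1f} kJ/mol")

for label, biases in [("unbiased", []), ("ratchet", [RatchetBias(k=5.0, direction=1)])]:
    crossed = 0
    for seed in range(5):
        res = integrate(pot, [RatchetBias(k=5.0, direction=1)] if label == "ratchet" else [],
                        LangevinParams(seed=seed), 100_000, record_stride=100, s0=left)
        if (res.cv[:, 0] > right - 1.0).any():
            crossed += 1
    print(f"{label:9s}: {crossed}/5 runs reached the target well within 1 ns")

print("The pawl never pushes past new ground; it only forbids regression, so the")
print("system climbs the barrier by rectified diffusion instead of waiting for a")
print("rare spontaneous crossing.")
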