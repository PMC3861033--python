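"""Mode-resolved linear stability of the unpolarized control cell.

Computes the homogeneous steady state for the control parameter set and
the leading growth rate per spherical-harmonic degree l.  A positive
rate at l = 1 (and only there) means small random fluctuations grow
directly into a single polar cap rather than multiple patches.
"""

import numpy as np

from gdipol import control_parameters, growth_spectrum, homogeneous_steady_state

p = control_parameters()
base = homogeneous_steady_state(p)
print("unpolarized state (membrane, um^-2):",
      "mT=%.3f mD=%.3f mB=%.3f mBG=%.3f" % tuple(base.m))
print("unpolarized membrane Cdc42-GTP fraction: %.3f" % base.cdc42gtp_fraction(p))

for closure in ("full", "reservoir"):
    spec = growth_spectrum(p, l_max=10, base=base, cytosol=closure)
    print(f"\ncytosol closure: {closure}")
    print("  l :", " ".join(f"{l:>8d}" for l in spec.l[:6]))
    print("  s :", " ".join(f"{s:8.5f}" for s in spec.re[:6]), "(1/s)")
    print(f"  dominant degree: l = {spec.dominant_l}, "
          f"sigma = {spec.re[spec.dominant_l]:.5f} 1/s")

print("""
Only l = 1 grows: a single cap emerges with e-folding time ~1/sigma_1
(about 4-5 minutes).  The 'full' closure is the exact linearization of
the bulk-surface dynamics; 'reservoir' neglects cytosolic depletion
under the growing cap and reproduces the classic reported rate.""")
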