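"""Phase-amplitude coupling metrics on a synthetic theta-gamma signal.

Builds a 6 Hz rhythm whose 60 Hz carrier amplitude follows the slow
phase, then quantifies the coupling with the modulation index, locates it
on the comodulogram, and reads off the preferred phase.
"""

import numpy as np

from thetanest.analysis import (comodulogram, modulation_index,
                                preferred_phase)
from thetanest.fixtures import make_pac_signal

fs = 1000.0
_, coupled = make_pac_signal(duration_s=20.0, fs=fs, f_phase_hz=6.0,
                             f_amp_hz=60.0, depth=1.0, noise_sd=0.1, seed=5)
_, flat = make_pac_signal(duration_s=20.0, fs=fs, depth=0.0, noise_sd=0.1,
                          seed=5)

mi_c = modulation_index(coupled, fs).modulation_index
mi_f = modulation_index(flat, fs).modulation_index
print(f"modulation index, coupled signal:   {mi_c:.4f}")
print(f"modulation index, unmodulated ctrl: {mi_f:.4f}")

pc, ac, mi, seed = comodulogram(coupled, fs, seed=0)
i, j = np.unravel_index(np.argmax(mi), mi.shape)
print(f"comodulogram maximum: phase band {pc[i]:.1f} Hz, "
      f"amplitude band {ac[j]:.0f} Hz (construction: 6 and 60 Hz)")

bands, centers, hists, pref = preferred_phase(coupled, fs)
k = np.argmin(np.abs(bands - 60.0))
print(f"preferred theta phase of the 60 Hz band: {pref[k]:+.2f} rad "
      "(0 = theta peak, matching the constructed envelope)")
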