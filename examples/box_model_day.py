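"""One simulated day in the mixed-layer box, now and at high CO2.

Runs the 3-h box model for a single day with a prescribed diurnal SST
cycle and light-driven net community production, first with DIC
equilibrated to the preindustrial atmosphere (284 ppm) and then to a
high-emission end-of-century value (1090 ppm).  The same physical and
biological forcing produces a much larger diurnal pCO2 cycle at high CO2
because ocean carbon uptake raises the temperature sensitivity of pCO2 —
while the aragonite-saturation cycle shrinks.
"""

import numpy as np

from dielco2 import (BoxState, ForcingSeries, NCPParams, SeawaterState,
                     equilibrate_to_atmosphere, run)
from dielco2.synthgen import DIURNAL_SHAPE

sst = 18.0 + 0.4 * DIURNAL_SHAPE  # 0.4 °C peak-to-peak, max at 15:00
par = np.array([0, 0, 0, 0.5, 1.0, 0.8, 0.2, 0.0])
ncp = NCPParams(gross_daily=1.5)  # balanced: daylight drawdown, night return

template = SeawaterState(18.0, 35.0, 2000.0, 2300.0)
for xco2 in (284.0, 1090.0):
    eq = equilibrate_to_atmosphere(template, xco2)
    box = BoxState(eq, depth=30.0)
    out = run(box, ForcingSeries(xco2=xco2, sst=sst, u10=np.full(8, 7.0),
                                 par=par), ncp)
    amp_p = float(out.pco2.max() - out.pco2.min())
    amp_o = float(out.omega_arag.max() - out.omega_arag.min())
    peak_slot = int(np.argmax(out.pco2[0]))
    print(f"background {xco2:6.0f} ppm: diurnal pCO2 amplitude "
          f"{amp_p:5.2f} µatm (max at {3*peak_slot:02d}:00), "
          f"Omega_arag amplitude {amp_o:.4f}")

print("\nsame forcing, ~3x the pCO2 amplitude at high CO2: the amplification")
print("is pure carbonate chemistry (buffer-factor growth), not the weather.")
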