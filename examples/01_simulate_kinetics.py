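"""Simulate the caffeine network after a 200 mg capsule.

Builds literature-informed rate constants, solves the one-compartment
cascade in closed form, and prints when each methylxanthine peaks in the
body.  Peak times and heights are what the finger-sweat time series
ultimately encode, once the fluctuating sweat volumes are accounted for.
"""

import numpy as np

import sweatpk as sp

rates = sp.RateConstants(k1=4.0, k2=0.06, k3=0.012, k4=0.008, k5=0.02,
                         k6=0.12, k7=0.05, k8=0.08)
times = np.linspace(0, 24, 2000)
traj = sp.simulate(rates, sp.PKConstants(dose=200.0), sp.InitialState(),
                   times)

print("species        peak time (h)   peak conc (ug/L)")
for j, species in enumerate(sp.SPECIES):
    i = int(np.argmax(traj.conc[:, j]))
    print(f"{species:<14} {times[i]:>10.2f} {traj.conc[i, j]:>16.1f}")
frac = rates.k2 / rates.kappa
print(f"\nparaxanthine route carries k2/kappa = {frac:.0%} of caffeine "
      "turnover;")
print("caffeine peaks fast (absorption-limited), the products hours later "
      "(conversion-limited).")
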