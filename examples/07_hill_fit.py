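"""Fit a Hill concentration-inhibition curve and extract the IC50, plus the
fold-activation statistic."""

import numpy as np

from poreflux.ephys import fold_activation, hill_fit
from poreflux.synth import gen_dose_response

doses = np.geomspace(0.1, 1000.0, 10)                  # µM
df = gen_dose_response(ic50=7.0, hill_coefficient=1.0, concentrations=doses,
                       noise_sd=3.0, seed=2)

fit = hill_fit(df.dose_uM, df.pct_inhibition)
print(f"IC50 (x_1/2)     : {fit.x_half:.2f} ± {fit.x_half_stderr:.2f} µM")
print(f"Hill coefficient : {fit.rate:.2f} ± {fit.rate_stderr:.2f}")

fa = fold_activation(I_basal=2.0, I_activated=206.0)
print(f"fold activation  : {fa.FA:.0f}x")
# %inh(x) = 100/(1 + (x_half/x)^rate); the planted IC50 is 7 µM, and
# FA = I_activated/I_basal for a ligand-activated current.
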