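"""Recover the time constant tau from perceived-length data.

A synthetic dataset is generated at tau = 0.10 s over an interval sweep
with 0.3-cm report noise, then refit. On real data, supply a CSV with
columns length_cm,time_s,perceived_cm to `fit_tau` (or the `saltation
fit-tau` command).
"""

import numpy as np

from saltation import fit_tau, make_fixture_dataset

design = [(10.0, t) for t in np.linspace(0.05, 1.0, 50)]

clean = make_fixture_dataset(tau_true=0.10, design=design, noise_sd=0.0)
print(f"noiseless fit : tau = {fit_tau(clean).tau:.6f} s (exact recovery)")

noisy = make_fixture_dataset(tau_true=0.10, design=design, noise_sd=0.3, seed=1)
fit = fit_tau(noisy)
print(f"noisy fit     : tau = {fit.tau:.4f} s, residual SS = {fit.rss:.2f} cm^2, "
      f"n = {fit.n}")
# with 0.3-cm report noise and 50 records the estimate is typically
# within 10% of the generating value
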