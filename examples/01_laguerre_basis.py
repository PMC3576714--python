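"""Build a discrete orthonormal Laguerre basis and inspect its properties.

The basis compresses Volterra kernels: instead of one free parameter per
lag bin, a kernel is a combination of a few smooth decaying functions.
"""

import numpy as np

import lvcontrol as lv

basis = lv.build_basis(alpha=0.95, n_basis=3, n_lags=1000, dt=0.001)
print(f"basis: alpha={basis.alpha}, L={basis.n_basis}, "
      f"memory={basis.memory_s:.1f}s in {basis.n_lags} bins of {basis.dt*1e3:.0f} ms")

# Orthonormality: the Gram matrix of the tabulated rows is the identity.
gram = basis.gram()
print("max |Gram - I| =", np.max(np.abs(gram - np.eye(3))))

# Time extent grows with alpha: lag bin containing 99% of the energy.
for alpha in (0.6, 0.9, 0.95):
    vals = lv.evaluate_laguerre(alpha, 2, np.arange(1000))
    energy = np.cumsum(vals ** 2)
    m99 = np.searchsorted(energy, 0.99 * energy[-1])
    print(f"alpha={alpha}: 99% of order-2 energy within {m99} ms")

# Event-driven convolution: two pulses 50 ms apart; the second event sees
# the first one through L_l(50), the first event sees nothing.
train = lv.EventTrain([0.0, 0.05], [150.0, 150.0])
print("v at first event: ", lv.convolve_events(basis, train, 0))
print("v at second event:", lv.convolve_events(basis, train, 1),
      "(= 150 * L_l(50))")
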