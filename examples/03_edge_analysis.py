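"""Run robust edge analysis on the CT-like channel of a phantom.

REA decomposes the image into a Canny edge map, a smooth slope field
recovered by energy descent, and a per-pixel energy map; the descent trace
is non-increasing by construction.
"""

import numpy as np

from btfsc.edges import optimize_slopes
from btfsc.phantom import PhantomSpec, generate_phantom_pair

pair = generate_phantom_pair(PhantomSpec(noise_sigma=10.0, seed=2))
res = optimize_slopes(pair.ct)

trace = np.asarray(res.energy_trace)
print(f"edge pixels        : {int(res.edges.sum())}")
print(f"smooth pixels      : {int(res.smooth_flag.sum())} of {res.smooth_flag.size}")
print(f"descent iterations : {len(trace)} (converged={res.converged})")
print(f"energy first->last : {trace[0]:.4f} -> {trace[-1]:.4f}")
print(f"trace non-increasing: {bool(np.all(np.diff(trace) <= 1e-9))}")
print("\nThe energy map highlights non-smooth (edge-carrying) regions; it is")
print("what the fusion stage optionally injects into its CT branch.")
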