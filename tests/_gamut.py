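"""Sample Lab images inside a stain basis's representable gamut.

The clamped 8-bit display transform can only encode densities in
[0, 1]; a round-trip check therefore draws random density triples in
that range whose re-mixed optical densities also stay in [0, 1], and
maps them to Lab channel values.
"""

import numpy as np

from earcount.enhance import LabImage

_LN256 = np.log(256.0)


def random_lab_in_gamut(od, rng, shape=(8, 8)):
    n = shape[0] * shape[1]
    dens = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, 0.95, size=(n - filled, 3))
        od_vals = cand @ od.C
        ok = np.all((od_vals >= 0.0) & (od_vals <= 1.0), axis=1)
        k = int(ok.sum())
        dens[filled : filled + k] = cand[ok]
        filled += k
    od_vals = dens.reshape(*shape, 3) @ od.C
    lab = np.exp(-od_vals * _LN256) * 256.0 - 1.0
    return LabImage(np.clip(lab, 0.0, 255.0))
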