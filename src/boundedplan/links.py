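"""Link functions relating information costs (bits) to activity units.

The same four links are used generatively (synthetic cohorts) and in the
regression design, so a correctly specified noiseless fit interpolates
exactly: identity, square, log(1 + x), and the logistic sigmoid
sigma(x) = 1 / (1 + exp(-x)) applied element-wise.
"""

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


LINKS = {
    "linear": lambda x: np.asarray(x, dtype=float),
    "quadratic": lambda x: np.asarray(x, dtype=float) ** 2,
    "logarithmic": lambda x: np.log1p(np.asarray(x, dtype=float)),
    "sigmoidal": _sigmoid,
}
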