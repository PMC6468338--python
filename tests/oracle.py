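"""Independent test oracle: brute-force maximum-likelihood population size.

Under the classical two-sample model, the number of marked individuals R
seen in a second sample of size C from a population of N containing M
marked individuals is hypergeometric.  The maximum-likelihood N is found
here by exhaustive search over the likelihood — deliberately ignorant of
any closed form."""

import numpy as np
from scipy.stats import hypergeom


def hypergeom_mle(m: int, c: int, r: int) -> int:
    """argmax over N of P(R = r | N, M = m, C = c)."""
    lo = m + c - r  # smallest population consistent with the observed overlap
    hi = (m * c) // max(r, 1) + 5
    candidates = np.arange(lo, hi + 1)
    loglik = hypergeom.logpmf(r, candidates, m, c)
    return int(candidates[np.argmax(loglik)])
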