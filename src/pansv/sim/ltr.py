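"""Forward Jukes-Cantor simulation of LTR 5'/3' divergence.

At insertion the two LTR copies of a retrotransposon are identical; each
then accumulates substitutions independently. Under Jukes-Cantor the chance
that a site still carries its ancestral base after T years at rate r is
1/4 + 3/4 exp(-4 r T / 3); the observed between-copy divergence lambda has
expectation 3/4 (1 - exp(-8 r T / 3)), the exact inverse of the dating
estimator K = -0.75 ln(1 - 4 lambda / 3), T = K / 2r.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..estimators import DEFAULT_SUBSTITUTION_RATE


def simulate_ltr_pairs(true_time_years: float,
                       rate: float = DEFAULT_SUBSTITUTION_RATE,
                       n_pairs: int = 200, ltr_length: int = 5000,
                       rng: Optional[np.random.Generator] = None,
                       seed: int = 0) -> np.ndarray:
    """Observed per-site divergences for ``n_pairs`` independent LTR pairs."""
    if true_time_years < 0:
        raise ValueError("insertion time cannot be negative")
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    stay = 0.25 + 0.75 * np.exp(-4.0 * rate * true_time_years / 3.0)

    lams = np.empty(n_pairs)
    for i in range(n_pairs):
        ancestor = rng.integers(0, 4, size=ltr_length)
        copies = []
        for _ in range(2):
            state = ancestor.copy()
            mutated = rng.random(ltr_length) >= stay
            # a substituted site ends in one of the three other bases
            shift = rng.integers(1, 4, size=int(mutated.sum()))
            state[mutated] = (state[mutated] + shift) % 4
            copies.append(state)
        lams[i] = float(np.mean(copies[0] != copies[1]))
    return lams
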