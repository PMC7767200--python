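"""Independent high-precision oracle for the line-FRAP recovery series.

Evaluates the alternating series directly from the factorial definition with
50-digit decimal arithmetic — no recursion, no shared code with the
production implementation.
"""

import math
from decimal import Decimal, getcontext

getcontext().prec = 50


def recovery_series_oracle(t, D, K0, r0e, r0c, n_terms: int = 50) -> float:
    """Sum_{n<n_terms} (-K0)^n/n! * r0e * (n r0c^2 + r0e^2 + 8 n D t)^(-1/2),
    evaluated in 50-digit decimals."""
    t, D, K0, r0e, r0c = (Decimal(str(v)) for v in (t, D, K0, r0e, r0c))
    total = Decimal(0)
    for n in range(n_terms):
        radicand = n * r0c**2 + r0e**2 + 8 * n * D * t
        term = ((-K0) ** n / Decimal(math.factorial(n))
                * r0e / radicand.sqrt())
        total += term
    return float(total)


def mixture_oracle(t, comps, K0, r0e, r0c) -> float:
    """Weighted mixture of single-species oracles; ``comps`` is a list of
    (D, weight)."""
    return sum(w * recovery_series_oracle(t, D, K0, r0e, r0c)
               for D, w in comps)
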