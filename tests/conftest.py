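import math

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def study_cohort() -> pd.DataFrame:
    """Cohort table matching the published counts: 156 therapy-related
    myeloid neoplasm samples (77 t-AML with 15 mutated, 79 t-MDS with 16
    mutated) and 228 de-novo controls with 1 mutated."""
    rows = []
    i = 0

    def add(n, group, subtype, n_mut):
        nonlocal i
        for k in range(n):
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "group": group,
                    "subtype": subtype,
                    "PPM1D": int(k < n_mut),
                }
            )
            i += 1

    add(77, "t-MN", "t-AML", 15)
    add(79, "t-MN", "t-MDS", 16)
    add(228, "de novo", "de novo", 1)
    return pd.DataFrame(rows)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Independent brute-force two-sided Fisher p by hypergeometric enumeration.

    Enumerates every table with the observed margins and sums the point
    probabilities that do not exceed the observed table's probability.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # P(upper-left cell = x) under fixed margins
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1.0 + 1e-7):
            total += px
    return min(total, 1.0)
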