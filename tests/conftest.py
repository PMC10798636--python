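"""Shared fixtures and independent numeric oracles for the test suite."""

import hypothesis
import numpy as np
import pytest

from nutriq import GrowthContext

hypothesis.settings.register_profile(
    "ci", hypothesis.settings(derandomize=True, max_examples=50, deadline=None)
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def ctx_demo() -> GrowthContext:
    """The worked-example context: κt=4, φ0=0.1, φR_max=0.6 ⇒ λmax=2."""
    return GrowthContext(kappa_t=4.0, phi_0=0.1, phi_R_max=0.6)


def bisect_flux_balance(ctx: GrowthContext, kappa_n: float, tol: float = 1e-14):
    """Independent oracle: solve κt(φR−φ0) = κn(φR_max−φR) by bisection.

    Deliberately avoids the closed-form solution so it can check it.
    Returns (phi_R, growth_rate).
    """

    def imbalance(phi_r: float) -> float:
        return ctx.kappa_t * (phi_r - ctx.phi_0) - kappa_n * (ctx.phi_R_max - phi_r)

    lo, hi = ctx.phi_0, ctx.phi_R_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if imbalance(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    phi_r = 0.5 * (lo + hi)
    return phi_r, ctx.kappa_t * (phi_r - ctx.phi_0)


def random_context(rng: np.random.Generator) -> GrowthContext:
    """Draw a random valid growth context."""
    phi_0 = rng.uniform(0.0, 0.5)
    phi_r_max = rng.uniform(phi_0 + 0.05, 1.0)
    kappa_t = rng.uniform(0.5, 10.0)
    return GrowthContext(kappa_t=kappa_t, phi_0=phi_0, phi_R_max=phi_r_max)
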