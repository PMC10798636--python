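"""Steady-state bacterial growth laws with plastic nutrient quality.

The model balances two proteome-limited fluxes. Translation produces new
protein at rate ``κt·(φR − φ0)``, where ``φR`` is the ribosomal (plus
co-scaling biosynthesis) proteome fraction, ``φ0`` a growth-rate-independent
offset, and ``κt`` the translational capacity. Nutrient uptake and
catabolism supply precursors at rate ``κn·φP``, where ``φP`` is the
catabolic P-sector and ``κn`` the nutrient quality of the substrate. The
two sectors compete for a bounded share of the proteome,
``φR + φP = φR_max``, so at steady state the growth rate follows a
Monod-like law in nutrient quality:

    λ = λmax · κn / (κn + κt),        λmax = κt·(φR_max − φ0).

The plasticity extension decomposes the P-sector: only a fraction ``f`` of
it consists of transporters/enzymes specific to the substrate actually
being consumed (the core C*-sector); the remainder is an "adaptability"
sector ``φAD = φP·(1 − f)`` of preparatory proteins (alternative uptake
systems, stress response, motility). The effective nutrient quality is
then a regulated, plastic property,

    κn = f · κn*,

with ``κn*`` the core quality set by enzyme kinetics alone. Raising ``f``
(e.g. by swapping in a strong promoter for the substrate-specific operon)
raises the growth rate at the expense of the adaptability reserve.

All proteome fractions are dimensionless (fractions of total protein);
κt, κn, κn* and λ carry units of 1/h (per unit proteome fraction for the
capacities). Validation is strict: out-of-range parameters raise
:class:`~nutriq.errors.DomainError` rather than being clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, InfeasibleObservationError

__all__ = [
    "GrowthContext",
    "SubstrateParams",
    "SectorAllocation",
    "effective_nutrient_quality",
    "growth_rate_closed_form",
    "steady_state_allocation",
    "infer_kappa_n",
    "predict_promoter_swap",
    "adaptability_fraction",
]


@dataclass(frozen=True)
class GrowthContext:
    """Global (substrate-independent) growth-law parameters.

    Parameters
    ----------
    kappa_t
        Translational capacity, 1/h per unit proteome fraction; > 0.
    phi_0
        Offset ribosomal fraction extrapolated to zero growth; in [0, 1).
    phi_R_max
        Maximum combined R+P proteome fraction; in (phi_0, 1].

    Derived attributes
    ------------------
    lambda_max = kappa_t·(phi_R_max − phi_0) is the maximum growth rate;
    phi_fixed = 1 − (phi_R_max − phi_0) is the growth-rate-invariant
    proteome fraction, so lambda_max = (1 − phi_fixed)·kappa_t by
    construction.
    """

    kappa_t: float
    phi_0: float
    phi_R_max: float

    def __post_init__(self) -> None:
        if not self.kappa_t > 0:
            raise DomainError(f"kappa_t must be > 0, got {self.kappa_t}")
        if not 0 <= self.phi_0 < self.phi_R_max <= 1:
            raise DomainError(
                "require 0 <= phi_0 < phi_R_max <= 1, got "
                f"phi_0={self.phi_0}, phi_R_max={self.phi_R_max}"
            )

    @property
    def lambda_max(self) -> float:
        """Maximum growth rate κt·(φR_max − φ0), 1/h."""
        return self.kappa_t * (self.phi_R_max - self.phi_0)

    @property
    def phi_fixed(self) -> float:
        """Growth-rate-invariant proteome fraction 1 − (φR_max − φ0)."""
        return 1.0 - (self.phi_R_max - self.phi_0)


@dataclass(frozen=True)
class SubstrateParams:
    """Per-substrate nutrient-quality parameters.

    ``kappa_n_star`` is the core nutrient quality set by the kinetics of
    the substrate-specific transporters/enzymes; ``f`` in (0, 1] is the
    expression fraction of those proteins within the P-sector. The
    effective quality entering the growth law is ``kappa_n = f·kappa_n_star``.
    """

    name: str
    kappa_n_star: float
    f: float

    def __post_init__(self) -> None:
        if not self.kappa_n_star > 0:
            raise DomainError(f"kappa_n_star must be > 0, got {self.kappa_n_star}")
        if not 0 < self.f <= 1:
            raise DomainError(f"f must be in (0, 1], got {self.f}")

    @property
    def kappa_n(self) -> float:
        """Effective nutrient quality f·κn*, 1/h per unit fraction."""
        return self.f * self.kappa_n_star


@dataclass(frozen=True)
class SectorAllocation:
    """Steady-state proteome partition and the growth rate it sustains.

    ``growth_rate`` is the steady-state λ (the spec's ``lambda`` field;
    renamed because ``lambda`` is a Python keyword).
    """

    phi_R: float
    phi_P: float
    phi_C_star: float
    phi_AD: float
    growth_rate: float

    def __post_init__(self) -> None:
        for name in ("phi_R", "phi_P", "phi_C_star", "phi_AD"):
            value = getattr(self, name)
            if not -1e-12 <= value <= 1 + 1e-12:
                raise DomainError(f"{name} must lie in [0, 1], got {value}")
        if self.growth_rate < 0:
            raise DomainError(f"growth_rate must be >= 0, got {self.growth_rate}")
        if self.phi_C_star > self.phi_P + 1e-12:
            raise DomainError("phi_C_star cannot exceed phi_P")


def effective_nutrient_quality(kappa_n_star: float, f: float) -> float:
    """Effective nutrient quality κn = f·κn*.

    Raises :class:`DomainError` unless ``kappa_n_star > 0`` and
    ``0 < f <= 1``.
    """
    if not kappa_n_star > 0:
        raise DomainError(f"kappa_n_star must be > 0, got {kappa_n_star}")
    if not 0 < f <= 1:
        raise DomainError(f"f must be in (0, 1], got {f}")
    return f * kappa_n_star


def growth_rate_closed_form(ctx: GrowthContext, kappa_n: float) -> float:
    """Steady-state growth rate λ = λmax·κn/(κn + κt).

    Strictly increasing and concave in ``kappa_n``; λ(0) = 0 and
    λ → λmax as κn → ∞.
    """
    if kappa_n < 0:
        raise DomainError(f"kappa_n must be >= 0, got {kappa_n}")
    if math.isinf(kappa_n):
        return ctx.lambda_max
    return ctx.lambda_max * kappa_n / (kappa_n + ctx.kappa_t)


def steady_state_allocation(
    ctx: GrowthContext, substrate: SubstrateParams
) -> SectorAllocation:
    """Solve the flux balance κt(φR − φ0) = κn(φR_max − φR) for the sectors.

    The balance is linear in φR, giving
    φR = (κt·φ0 + κn·φR_max)/(κn + κt); the P-sector takes the remaining
    headroom φP = φR_max − φR, of which the fraction ``substrate.f`` is the
    core catabolic C*-sector and the rest the adaptability sector φAD.
    The returned growth rate equals :func:`growth_rate_closed_form`.
    """
    kappa_n = substrate.kappa_n
    phi_R = (ctx.kappa_t * ctx.phi_0 + kappa_n * ctx.phi_R_max) / (
        kappa_n + ctx.kappa_t
    )
    phi_P = ctx.phi_R_max - phi_R
    phi_C_star = substrate.f * phi_P
    phi_AD = phi_P - phi_C_star
    growth_rate = ctx.kappa_t * (phi_R - ctx.phi_0)
    return SectorAllocation(
        phi_R=phi_R,
        phi_P=phi_P,
        phi_C_star=phi_C_star,
        phi_AD=phi_AD,
        growth_rate=growth_rate,
    )


def infer_kappa_n(ctx: GrowthContext, lambda_obs: float) -> float:
    """Invert the growth law: κn = κt·λ/(λmax − λ).

    ``lambda_obs`` must lie in [0, λmax); observing λ ≥ λmax is
    incompatible with the model and raises
    :class:`InfeasibleObservationError`.
    """
    if lambda_obs < 0:
        raise DomainError(f"lambda_obs must be >= 0, got {lambda_obs}")
    if lambda_obs >= ctx.lambda_max:
        raise InfeasibleObservationError(
            f"observed growth rate {lambda_obs} /h is not below the model's "
            f"maximum {ctx.lambda_max} /h"
        )
    return ctx.kappa_t * lambda_obs / (ctx.lambda_max - lambda_obs)


def predict_promoter_swap(
    ctx: GrowthContext, substrate: SubstrateParams, f_new: float
) -> float:
    """Growth rate after re-setting the expression fraction to ``f_new``.

    Models a promoter-swap intervention: the core quality κn* of the
    substrate is untouched, only the expression fraction of its dedicated
    transporters/enzymes changes, so λ_new = λ(f_new·κn*). Monotone
    non-decreasing in ``f_new``; f_new = 1 maximizes the prediction.
    """
    return growth_rate_closed_form(
        ctx, effective_nutrient_quality(substrate.kappa_n_star, f_new)
    )


def adaptability_fraction(phi_P: float, f: float) -> float:
    """Adaptability sector φAD = φP − φC* = φP·(1 − f)."""
    if not 0 <= phi_P <= 1:
        raise DomainError(f"phi_P must lie in [0, 1], got {phi_P}")
    if not 0 < f <= 1:
        raise DomainError(f"f must be in (0, 1], got {f}")
    return phi_P * (1.0 - f)
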