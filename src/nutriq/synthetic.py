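"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its arguments (including the seed),
emulating the statistical structure of the corresponding wet-lab
measurement with known ground truth:

* OD600 growth curves — exponential (or piecewise diauxic) dynamics with
  multiplicative lognormal noise, the natural error model for a
  positive-valued density readout;
* proteomics integration tables — a phenomenological log-linear inverse
  relation between a substrate's transporter copy number at slow growth
  and the growth rate on that substrate (log N = a − b·λ + ε), plus decoy
  genes present in only one table to exercise the join. The relation is
  generated phenomenologically rather than derived from the growth-law
  model, because the measured anticorrelation is the hypothesis under
  test, not an assumption the generator should hard-code;
* CFU plate counts — Poisson sampling of colonies at the expected count
  density × plated volume / dilution;
* titration curves — the model curve plus additive Gaussian noise
  truncated at zero.

Sub-streams are derived deterministically from one integer seed per
dataset, so regenerating any table is reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .growth_law import GrowthContext
from .phenotype import CFUObservation, ODSeries
from .titration import TitrationCurve, titration_curve

__all__ = [
    "ProteomicsTables",
    "gen_od_series",
    "gen_diauxic_series",
    "gen_proteomics",
    "gen_cfu",
    "gen_titration_data",
]


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv < 0:
        raise DomainError(f"noise_cv must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=n)


def gen_od_series(
    growth_rate: float,
    od0: float,
    t_grid,
    noise_cv: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> ODSeries:
    """Exponential OD600 curve od0·e^{λt} with multiplicative noise.

    ``noise_cv = 0`` yields the exact exponential (no RNG draw at all).
    """
    if growth_rate < 0:
        raise DomainError(f"growth_rate must be >= 0, got {growth_rate}")
    if not od0 > 0:
        raise DomainError(f"od0 must be > 0, got {od0}")
    t = np.asarray(t_grid, dtype=float)
    od = od0 * np.exp(growth_rate * t)
    od = od * _lognormal_noise(np.random.default_rng(seed), noise_cv, t.size)
    return ODSeries(times=t, od600=od, label=label)


def gen_diauxic_series(
    lambda1: float,
    od_shift: float,
    lag: float,
    lambda2: float,
    t_grid,
    noise_cv: float = 0.0,
    seed: int = 0,
    od0: float = 0.02,
    label: str = "",
) -> ODSeries:
    """Two-phase (diauxic) OD600 curve with a plateau of known duration.

    Growth at ``lambda1`` from ``od0`` until the OD reaches ``od_shift``
    (at t1 = ln(od_shift/od0)/λ1), a flat lag of ``lag`` hours, then
    growth at ``lambda2``. The true lag is recoverable by the diauxic
    pipeline to within one grid step on noiseless data. ``lambda2 = 0``
    produces a deliberately flat second phase (a negative fixture for the
    no-regrowth error path).
    """
    if not lambda1 > 0:
        raise DomainError(f"lambda1 must be > 0, got {lambda1}")
    if lambda2 < 0:
        raise DomainError(f"lambda2 must be >= 0, got {lambda2}")
    if lag < 0:
        raise DomainError(f"lag must be >= 0, got {lag}")
    if not 0 < od0 < od_shift:
        raise DomainError("require 0 < od0 < od_shift")
    t = np.asarray(t_grid, dtype=float)
    t1 = math.log(od_shift / od0) / lambda1
    if t1 >= t[-1]:
        raise DomainError(
            f"od_shift is unreachable: first phase would end at t={t1:.3g} h, "
            f"beyond the grid end {t[-1]:.3g} h"
        )
    log_od = np.where(
        t < t1,
        math.log(od0) + lambda1 * t,
        np.where(
            t < t1 + lag,
            math.log(od_shift),
            math.log(od_shift) + lambda2 * (t - t1 - lag),
        ),
    )
    od = np.exp(log_od) * _lognormal_noise(np.random.default_rng(seed), noise_cv, t.size)
    return ODSeries(times=t, od600=od, label=label)


@dataclass(frozen=True)
class ProteomicsTables:
    """Generated proteomics-integration dataset with its ground truth.

    ``abundance`` (gene_id, copies_per_cell, length_aa), ``foldchange``
    (gene_id, fold_change), ``substrates`` (substrate, gene_id,
    growth_rate) are the pipeline inputs; ``truth`` records every latent
    value (including realized copies_slow and cost_aa) per substrate.
    """

    abundance: pd.DataFrame
    foldchange: pd.DataFrame
    substrates: pd.DataFrame
    truth: pd.DataFrame


def gen_proteomics(
    n_substrates: int = 20,
    a: float = 11.0,
    b: float = 3.0,
    noise_cv: float = 0.2,
    fc_range: tuple[float, float] = (1.5, 8.0),
    length_range: tuple[int, int] = (300, 900),
    lambda_range: tuple[float, float] = (0.2, 1.2),
    n_decoys: int = 5,
    seed: int = 0,
) -> ProteomicsTables:
    """Generate abundance/fold-change/substrate tables with known truth.

    Per substrate: growth_rate ~ U(lambda_range); the realized transporter
    copy number at the slow reference is exp(a − b·growth_rate)·ε with
    unit-mean lognormal ε (CV ``noise_cv``); fold_change ~ U(fc_range) and
    copies_per_cell = copies_slow / fold_change so the pipeline's product
    reconstructs copies_slow exactly; length_aa ~ U{length_range}.
    ``n_decoys`` extra genes are placed in only one table each (cycling
    through the three tables) so the join must drop exactly that many
    distinct genes. ``b = 0`` gives the null model with no copies–growth
    relation.
    """
    if n_substrates < 3:
        raise DomainError(f"n_substrates must be >= 3, got {n_substrates}")
    if b < 0:
        raise DomainError(f"slope b must be >= 0, got {b}")
    if n_decoys < 0:
        raise DomainError(f"n_decoys must be >= 0, got {n_decoys}")
    for name, (lo, hi) in (
        ("fc_range", fc_range),
        ("lambda_range", lambda_range),
    ):
        if not 0 < lo <= hi:
            raise DomainError(f"invalid {name}: {(lo, hi)}")
    if not 1 <= length_range[0] <= length_range[1]:
        raise DomainError(f"invalid length_range: {length_range}")

    streams = np.random.SeedSequence(seed).spawn(5)
    rng_lambda, rng_noise, rng_fc, rng_len, _ = (
        np.random.default_rng(s) for s in streams
    )

    growth = rng_lambda.uniform(*lambda_range, size=n_substrates)
    eps = _lognormal_noise(rng_noise, noise_cv, n_substrates)
    copies_slow = np.exp(a - b * growth) * eps
    fold_change = rng_fc.uniform(*fc_range, size=n_substrates)
    copies_per_cell = copies_slow / fold_change
    length_aa = rng_len.integers(length_range[0], length_range[1] + 1, size=n_substrates)

    genes = [f"gene_{i + 1:03d}" for i in range(n_substrates)]
    substrate_names = [f"substrate_{i + 1:02d}" for i in range(n_substrates)]

    abundance = pd.DataFrame(
        {"gene_id": genes, "copies_per_cell": copies_per_cell, "length_aa": length_aa}
    )
    foldchange = pd.DataFrame({"gene_id": genes, "fold_change": fold_change})
    substrates = pd.DataFrame(
        {"substrate": substrate_names, "gene_id": genes, "growth_rate": growth}
    )
    truth = pd.DataFrame(
        {
            "substrate": substrate_names,
            "gene_id": genes,
            "growth_rate": growth,
            "copies_slow": copies_slow,
            "fold_change": fold_change,
            "length_aa": length_aa,
            "cost_aa": copies_slow * length_aa,
        }
    )

    # Decoy genes live in exactly one table each, cycling through the three.
    for k in range(n_decoys):
        gid = f"decoy_{k + 1:03d}"
        which = k % 3
        if which == 0:
            abundance = pd.concat(
                [abundance, pd.DataFrame(
                    {"gene_id": [gid], "copies_per_cell": [1000.0], "length_aa": [400]}
                )],
                ignore_index=True,
            )
        elif which == 1:
            foldchange = pd.concat(
                [foldchange, pd.DataFrame({"gene_id": [gid], "fold_change": [2.0]})],
                ignore_index=True,
            )
        else:
            substrates = pd.concat(
                [substrates, pd.DataFrame(
                    {"substrate": [f"decoy_substrate_{k + 1:02d}"],
                     "gene_id": [gid], "growth_rate": [0.5]}
                )],
                ignore_index=True,
            )
    return ProteomicsTables(
        abundance=abundance, foldchange=foldchange, substrates=substrates, truth=truth
    )


def gen_cfu(
    true_density_per_mL: float,
    dilution_factor: float,
    plated_volume_mL: float,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[CFUObservation]:
    """Poisson-distributed colony counts for replicate platings.

    Expected colonies per plate = density × volume / dilution; counts are
    independent across replicates. Expectations above 1e6 are refused
    (no countable plate holds a million colonies).
    """
    if not true_density_per_mL >= 0:
        raise DomainError("true_density_per_mL must be >= 0")
    if dilution_factor < 1 or not plated_volume_mL > 0 or n_replicates < 1:
        raise DomainError("invalid dilution/volume/replicate parameters")
    expected = true_density_per_mL * plated_volume_mL / dilution_factor
    if expected > 1e6:
        raise DomainError(
            f"expected plate count {expected:.3g} exceeds 1e6; increase the dilution"
        )
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected, size=n_replicates)
    return [
        CFUObservation(
            colonies=int(c),
            dilution_factor=dilution_factor,
            plated_volume_mL=plated_volume_mL,
        )
        for c in counts
    ]


def gen_titration_data(
    ctx: GrowthContext,
    kappa_n: float,
    n_points: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    mode: str = "hard_min",
) -> TitrationCurve:
    """Model titration curve plus additive Gaussian noise truncated at 0.

    ``noise_sd = 0`` reproduces :func:`nutriq.titration.titration_curve`
    exactly.
    """
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")
    clean = titration_curve(ctx, kappa_n, n_points, mode)
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = np.clip(clean.growth_rate + rng.normal(0.0, noise_sd, n_points), 0.0, None)
    return TitrationCurve(x=clean.x, growth_rate=noisy, mode=mode)
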