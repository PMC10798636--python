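"""Protein investment in substrate-specific catabolism vs growth rate.

Integrates three processed tables — absolute protein copy numbers in a
glucose reference condition (ribosome-profiling-derived), abundance
fold-changes from that condition to a slow carbon-limited reference
(λ ≈ 0.45 /h, mass-spectrometry-derived), and a curated map of each
substrate to its main transporter or first catabolic enzyme with the
wild-type growth rate on that substrate. For each substrate the copy
number of its dedicated protein at the slow reference is

    copies_slow = copies_per_cell × fold_change,

and its protein cost in amino acids per cell is

    cost_aa = copies_slow × length_aa.

The analysis then asks whether expression of a substrate's uptake
machinery anticipates the substrate's quality: a rank-ordered
anticorrelation (Spearman) between copies_slow (or cost_aa) and the
growth rate achieved on the substrate. Spearman is the primary statistic
because the claim is about rank ordering; Pearson on log cost is emitted
as a secondary check.

The slow reference growth rate is carried through as metadata only — the
fold-change table is assumed pre-selected for that condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, DataError, DomainError, StatisticsError

__all__ = [
    "REFERENCE_SLOW_GROWTH_RATE",
    "JoinResult",
    "CostGrowthResult",
    "join_datasets",
    "copies_at_reference",
    "protein_cost",
    "rank_correlation",
    "cost_growth_analysis",
]

logger = logging.getLogger(__name__)

#: Growth rate (1/h) of the slow carbon-limited reference condition to
#: which the fold-change table refers. Metadata annotation only.
REFERENCE_SLOW_GROWTH_RATE = 0.45

ABUNDANCE_COLUMNS = ("gene_id", "copies_per_cell", "length_aa")
FOLDCHANGE_COLUMNS = ("gene_id", "fold_change")
SUBSTRATE_COLUMNS = ("substrate", "gene_id", "growth_rate")


@dataclass(frozen=True)
class JoinResult:
    """Inner join of the three input tables plus bookkeeping.

    ``table`` has one row per surviving substrate with all joined
    columns; ``dropped_genes`` lists the distinct gene ids present in at
    least one input table but absent from the intersection;
    ``n_dropped_per_table`` counts, per input table, how many of its rows
    were lost.
    """

    table: pd.DataFrame
    dropped_genes: tuple[str, ...]
    n_dropped_per_table: dict[str, int]

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_genes)


@dataclass(frozen=True)
class CostGrowthResult:
    """Output of the full cost-vs-growth-rate integration.

    ``table`` columns: substrate, gene_id, copies_slow, cost_aa,
    growth_rate. The rank correlations pair copies_slow (resp. cost_aa)
    with growth_rate across substrates; ``pearson_log_cost`` is the
    secondary Pearson correlation of log(cost_aa) with growth_rate.
    """

    table: pd.DataFrame
    rho_copies: float
    p_copies: float
    rho_cost: float
    p_cost: float
    pearson_log_cost: float
    p_pearson_log_cost: float
    n_dropped: int
    reference_growth_rate: float = REFERENCE_SLOW_GROWTH_RATE


def _require_columns(df: pd.DataFrame, columns, label: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{label} table is missing column(s) {missing}")
    if df.empty:
        raise DataError(f"{label} table is empty")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise DataError(f"{label} table has duplicate gene_id(s) {dupes}")


def join_datasets(
    abundance: pd.DataFrame,
    foldchange: pd.DataFrame,
    substrates: pd.DataFrame,
) -> JoinResult:
    """Inner-join the three tables on ``gene_id``.

    Only genes present in all three tables survive ("proteins that show
    up in both datasets" plus the substrate curation). Dropped genes are
    reported, not silently discarded.
    """
    _require_columns(abundance, ABUNDANCE_COLUMNS, "abundance")
    _require_columns(foldchange, FOLDCHANGE_COLUMNS, "fold-change")
    _require_columns(substrates, SUBSTRATE_COLUMNS, "substrate")

    sets = {
        "abundance": set(abundance["gene_id"]),
        "foldchange": set(foldchange["gene_id"]),
        "substrates": set(substrates["gene_id"]),
    }
    common = sets["abundance"] & sets["foldchange"] & sets["substrates"]
    if not common:
        for label, genes in sets.items():
            logger.error("%s genes: %s", label, sorted(genes))
        raise AnalysisError(
            "no gene_id is shared by all three tables (empty intersection)"
        )

    merged = (
        substrates.merge(foldchange, on="gene_id", how="inner")
        .merge(abundance, on="gene_id", how="inner")
        .reset_index(drop=True)
    )
    dropped = tuple(sorted((set().union(*sets.values())) - common))
    per_table = {label: len(genes - common) for label, genes in sets.items()}
    if dropped:
        logger.info(
            "join dropped %d gene(s) absent from at least one table: %s",
            len(dropped),
            ", ".join(dropped),
        )
    return JoinResult(
        table=merged, dropped_genes=dropped, n_dropped_per_table=per_table
    )


def copies_at_reference(copies_per_cell, fold_change):
    """Copy number at the slow reference: copies_per_cell × fold_change.

    Inputs must be strictly positive (a zero reference abundance carries
    no information to scale). Accepts scalars or aligned arrays.
    """
    copies = np.asarray(copies_per_cell, dtype=float)
    fc = np.asarray(fold_change, dtype=float)
    if np.any(copies <= 0):
        raise DomainError("copies_per_cell must be > 0")
    if np.any(fc <= 0):
        raise DomainError("fold_change must be > 0")
    out = copies * fc
    return float(out) if out.ndim == 0 else out


def protein_cost(copies_slow, length_aa):
    """Protein cost in amino acids per cell: copies × protein length."""
    copies = np.asarray(copies_slow, dtype=float)
    length = np.asarray(length_aa, dtype=float)
    if np.any(copies < 0):
        raise DomainError("copies_slow must be >= 0")
    if np.any(length < 1):
        raise DomainError("length_aa must be >= 1")
    out = copies * length
    return float(out) if out.ndim == 0 else out


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    # Pearson correlation of average ranks; rank variance is never zero
    # here because constant inputs are rejected upstream.
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def rank_correlation(values_x, values_y) -> tuple[float, float]:
    """Spearman rank correlation with an exact small-sample p-value.

    Ties receive average ranks. For n <= 8 the two-sided p-value is exact,
    by enumeration of all n! orderings of one rank vector; for larger n it
    uses the t-distribution approximation with n−2 degrees of freedom.

    Raises :class:`StatisticsError` for n < 3 or a constant input.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("inputs must be paired 1-D vectors")
    n = x.size
    if n < 3:
        raise StatisticsError(f"need n >= 3 pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatisticsError("rank correlation is undefined for a constant vector")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)

    if n <= 8:
        target = abs(rho) - 1e-12
        hits = sum(
            1 for perm in permutations(ry) if abs(_spearman_rho(rx, np.array(perm))) >= target
        )
        p_value = hits / math.factorial(n)
    else:
        denom = 1.0 - rho * rho
        if denom <= 1e-15:  # |rho| = 1 up to roundoff
            p_value = 0.0
        else:
            t = rho * math.sqrt((n - 2) / denom)
            p_value = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(p_value, 1.0)


def cost_growth_analysis(joined) -> CostGrowthResult:
    """Full integration: reference copies → cost → rank anticorrelation.

    Parameters
    ----------
    joined
        A :class:`JoinResult` or its joined DataFrame (columns substrate,
        gene_id, copies_per_cell, fold_change, length_aa, growth_rate).

    Returns
    -------
    :class:`CostGrowthResult` with the per-substrate table and the
    Spearman correlations of copies_slow and cost_aa against growth rate.
    """
    if isinstance(joined, JoinResult):
        table = joined.table
        n_dropped = joined.n_dropped
    else:
        table = joined
        n_dropped = 0
    needed = {"substrate", "gene_id", "copies_per_cell", "fold_change",
              "length_aa", "growth_rate"}
    missing = needed - set(table.columns)
    if missing:
        raise DataError(f"joined table is missing column(s) {sorted(missing)}")
    if len(table) < 3:
        raise StatisticsError(
            f"need >= 3 substrates after the join, got {len(table)}"
        )
    if np.any(np.asarray(table["growth_rate"], dtype=float) <= 0):
        raise DomainError("growth_rate must be > 0 for every substrate")

    copies_slow = copies_at_reference(table["copies_per_cell"], table["fold_change"])
    cost_aa = protein_cost(copies_slow, table["length_aa"])
    growth = np.asarray(table["growth_rate"], dtype=float)

    out = pd.DataFrame(
        {
            "substrate": table["substrate"].to_numpy(),
            "gene_id": table["gene_id"].to_numpy(),
            "copies_slow": copies_slow,
            "cost_aa": cost_aa,
            "growth_rate": growth,
        }
    )
    rho_copies, p_copies = rank_correlation(copies_slow, growth)
    rho_cost, p_cost = rank_correlation(cost_aa, growth)
    pearson = stats.pearsonr(np.log(cost_aa), growth)
    return CostGrowthResult(
        table=out,
        rho_copies=rho_copies,
        p_copies=p_copies,
        rho_cost=rho_cost,
        p_cost=p_cost,
        pearson_log_cost=float(pearson.statistic),
        p_pearson_log_cost=float(pearson.pvalue),
        n_dropped=n_dropped,
    )
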