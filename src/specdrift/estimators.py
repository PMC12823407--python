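"""Trait-importance estimators, binning, enrichment and flattening analysis.

The unbiased estimator of a squared effect gamma^2 from a noisy estimate
gamma_hat ~ Normal(gamma, s^2) is gamma_hat^2 - s^2; it may be negative
and is deliberately not truncated, so that averages over genes remain
unbiased.  Heritability enrichment per gene bin uses z^2 - 1 as the
(proportional) heritability proxy, averaged within bins relative to the
all-gene mean, combined across traits by inverse-variance weighting, and
renormalized either to average to one or to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afs import SelectionGrid

__all__ = [
    "BinSummary",
    "EnrichmentTable",
    "unbiased_importance",
    "bin_by_key",
    "enrichment_from_z2",
    "flattening_analysis",
    "FlatteningResult",
]


def unbiased_importance(gamma_hat, se):
    """Unbiased estimate of gamma^2: gamma_hat^2 - se^2 (not truncated at 0)."""
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    out = gamma_hat**2 - se**2
    return float(out) if out.ndim == 0 else out


@dataclass
class BinSummary:
    """One bin of records sorted by a key: membership and within-bin means."""

    index: int
    ids: np.ndarray
    key_mean: float
    stat_means: dict
    stat_ses: dict

    @property
    def size(self) -> int:
        return len(self.ids)


def bin_by_key(
    records: pd.DataFrame,
    key: str,
    n_bins: int,
    id_col: str = "gene_id",
    stat_cols: list[str] | None = None,
) -> list[BinSummary]:
    """Sort records by ``key`` and split into n_bins contiguous, near-equal bins.

    Ties in the key are broken by the record id so the split is
    deterministic; bin sizes differ by at most one (larger bins first).
    """
    if len(records) == 0:
        raise ValueError("cannot bin an empty table")
    if n_bins > len(records):
        raise ValueError("more bins than records")
    ordered = records.sort_values([key, id_col], kind="mergesort").reset_index(drop=True)
    stat_cols = stat_cols or []
    splits = np.array_split(np.arange(len(ordered)), n_bins)
    out = []
    for b, rows in enumerate(splits):
        sub = ordered.iloc[rows]
        means = {c: float(sub[c].mean()) for c in stat_cols}
        ses = {
            c: float(sub[c].std(ddof=1) / np.sqrt(len(sub))) if len(sub) > 1 else np.nan
            for c in stat_cols
        }
        out.append(
            BinSummary(
                index=b,
                ids=sub[id_col].to_numpy(),
                key_mean=float(sub[key].mean()),
                stat_means=means,
                stat_ses=ses,
            )
        )
    return out


@dataclass
class EnrichmentTable:
    """Per-bin heritability enrichment estimates with SEs."""

    table: pd.DataFrame  # bin, key_mean, enrichment, se
    normalization: str

    def __post_init__(self) -> None:
        e = self.table["enrichment"].to_numpy()
        if self.normalization == "average_to_one":
            if abs(e.mean() - 1.0) > 1e-10:
                raise ValueError("average-to-one normalization violated")
        elif self.normalization == "sum_to_one":
            if abs(e.sum() - 1.0) > 1e-10:
                raise ValueError("sum-to-one normalization violated")
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")


def enrichment_from_z2(
    z2: np.ndarray,
    bins: list[BinSummary] | list[np.ndarray],
    gene_ids: np.ndarray,
    normalization: str = "average_to_one",
    key_means: np.ndarray | None = None,
) -> EnrichmentTable:
    """Heritability enrichment per gene bin from burden z^2 across traits.

    ``z2`` is (n_genes, n_traits) aligned with ``gene_ids``.  Per trait,
    each bin's mean of z^2 - 1 is divided by the all-gene mean of z^2 - 1;
    a trait whose all-gene mean is not positive carries no heritability
    signal and is dropped with a warning.  Bin SEs are the within-bin
    standard deviation of the relative values over sqrt(bin size); traits
    are combined by inverse-variance weighting and the combined estimates
    renormalized per ``normalization``.
    """
    z2 = np.asarray(z2, dtype=float)
    gene_ids = np.asarray(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    if isinstance(bins[0], BinSummary):
        members = [np.array([pos[g] for g in b.ids]) for b in bins]
        km = np.array([b.key_mean for b in bins])
    else:
        members = [np.asarray(b) for b in bins]
        km = np.arange(len(bins), dtype=float) if key_means is None else np.asarray(key_means)
    if any(m.size == 0 for m in members):
        raise ValueError("every bin must be nonempty")

    n_bins = len(members)
    est = np.zeros((n_bins, 0))
    ses = np.zeros((n_bins, 0))
    for t in range(z2.shape[1]):
        r = z2[:, t] - 1.0
        overall = r.mean()
        if overall <= 0:
            warnings.warn(f"trait {t} has no heritability signal (mean z2-1 <= 0); dropped")
            continue
        rel = r / overall
        e_t = np.array([rel[m].mean() for m in members])
        s_t = np.array([rel[m].std(ddof=1) / np.sqrt(m.size) for m in members])
        est = np.column_stack([est, e_t])
        ses = np.column_stack([ses, s_t])
    if est.shape[1] == 0:
        raise ValueError("no trait carries heritability signal")

    w = 1.0 / ses**2
    combined = (w * est).sum(axis=1) / w.sum(axis=1)
    combined_se = np.sqrt(1.0 / w.sum(axis=1))
    if normalization == "average_to_one":
        norm = combined.mean()
    elif normalization == "sum_to_one":
        norm = combined.sum()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    table = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "key_mean": km,
            "enrichment": combined / norm,
            "se": combined_se / abs(norm),
        }
    )
    return EnrichmentTable(table=table, normalization=normalization)


@dataclass
class FlatteningResult:
    """Expected heritability contributions per variant and per gene."""

    variant_alpha_sq: np.ndarray
    variant_contribution: np.ndarray
    gene_gamma: np.ndarray
    gene_total: np.ndarray


def flattening_analysis(
    gamma_grid: np.ndarray,
    n_variants_per_gene: int = 200,
    beta_sdlog: float = 1.25,
    grid: SelectionGrid | None = None,
    two_N: int = 2_000,
    mu: float | None = None,
    seed: int | np.random.Generator = 0,
) -> FlatteningResult:
    """Expected heritability contributions under mutation-selection balance.

    For each gene effect gamma on the grid, cis-variant effects are
    alpha = beta * gamma with log-normal beta (common draws across genes,
    so the gamma effect is isolated).  Each variant is fully focal-trait
    specific, so selection on it has strength alpha^2, and its expected
    contribution to heritability is 2 alpha^2 E[p(1-p)] with p from the
    equilibrium spectrum at s_het = alpha^2.  E[p(1-p)] is interpolated
    log-log across a selection grid spanning the realized alpha^2 range.

    Per-variant contributions plateau once selection dominates drift
    (E[p(1-p)] ~ mu/s_het makes the product approach 2 mu L), while
    per-gene totals keep growing with gamma because more of the gene's
    variants clear the contribution threshold.
    """
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if np.any(gamma_grid < 0) or np.any(np.diff(gamma_grid) <= 0):
        raise ValueError("gamma_grid must be nonnegative and strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if beta_sdlog <= 0:
        raise ValueError("beta distribution must not be degenerate at a point mass")
    beta = np.exp(rng.normal(0.0, beta_sdlog, size=n_variants_per_gene))

    pos = gamma_grid > 0
    alpha_sq = (np.outer(gamma_grid[pos], beta) ** 2).ravel()
    if grid is None:
        # smooth E[p(1-p)] curve from the loss-conditioned diffusion
        # stationary density (drift-scaled parameters of the reference
        # population preserved); smoothness in s matters here because the
        # per-gene totals integrate across the drift-to-selection crossover
        from .afs import REFERENCE_TWO_N, SelectionModel, diffusion_stationary_afs

        s_lo = max(alpha_sq.min() * 0.99, 1e-9)
        s_hi = alpha_sq.max() * 1.01
        scale = REFERENCE_TWO_N / two_N
        if mu is None:
            from .afs import DEFAULT_MU

            mu = DEFAULT_MU
        s_vals = np.geomspace(s_lo, s_hi, 40)

        def _epq(s: float) -> float:
            # once selection dominates (two_N * s_chain >= 100) the balance
            # limit E[p(1-p)] = mu/s holds to ~2% and is free of the
            # count-grid discretization error that creeps into the
            # discretized density at extreme selection
            if s * scale * two_N >= 100.0:
                return mu / s
            return diffusion_stationary_afs(
                SelectionModel(s * scale, mu * scale, two_N),
                condition_on_loss=True,
            ).mean_heterozygosity()

        het = np.array([_epq(s) for s in s_vals])
        grid_s = s_vals
    else:
        het = grid.mean_heterozygosities()
        grid_s = grid.grid
    log_e = np.interp(np.log(alpha_sq), np.log(grid_s), np.log(het))
    contrib = 2.0 * alpha_sq * np.exp(log_e)

    gene_total = np.zeros(gamma_grid.size)
    gene_total[pos] = contrib.reshape(pos.sum(), n_variants_per_gene).sum(axis=1)
    return FlatteningResult(
        variant_alpha_sq=alpha_sq,
        variant_contribution=contrib,
        gene_gamma=gamma_grid,
        gene_total=gene_total,
    )
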