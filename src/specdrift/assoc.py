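"""Simulated GWAS and LoF burden-test summary statistics.

All phenotypes are variance-standardized and covariate-free, so the
sampling standard error of a per-allele effect estimate at minor allele
frequency q in an effective sample of n_eff individuals is
1 / sqrt(2 n_eff q (1 - q)).  Association strength is measured by the
squared z-score, which is chi-squared with 1 degree of freedom under the
null; P values are carried in log10 space throughout so that magnitudes
like 1e-185 survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .afs import SelectionGrid, nearest_spectrum
from .effects import EffectMatrix, GeneModel

__all__ = [
    "GwasSummary",
    "BurdenSummary",
    "RealizedHeritabilityTable",
    "sample_gwas_frequency",
    "simulate_gwas_estimates",
    "pvalues_and_hits",
    "simulate_burden_test",
    "simulate_burden_panel",
    "subsample_summary",
    "realized_heritability_experiment",
]

LOG10 = np.log(10.0)
#: GWAS effective sample size used in the simulations.
DEFAULT_N_EFF = 1e7
#: Significance threshold for simulated GWAS hits.
DEFAULT_T = 1e-5
#: Haploid GWAS sample size (about 300,000 diploids).
DEFAULT_N_ALLELES = 600_000
#: Diploid sample size for simulated burden tests (exome-study scale).
DEFAULT_BURDEN_N = 400_000
#: Site-frequency upper bound for inclusion in the burden genotype.
DEFAULT_FREQ_CAP = 0.01


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def log10_sf_chi2(z2: np.ndarray) -> np.ndarray:
    """log10 of the upper chi-squared(1) tail at z2."""
    return chi2.logsf(z2, df=1) / LOG10


@dataclass
class GwasSummary:
    """Per-variant x per-trait GWAS summary statistics.

    ``alpha_hat`` and ``log10p`` are (n_variants, n_traits); ``se``,
    ``maf`` and ``pop_freq`` are per-variant (the standard error depends
    only on the allele frequency under the standardized-phenotype model).
    """

    alpha_hat: np.ndarray
    se: np.ndarray
    maf: np.ndarray
    pop_freq: np.ndarray | None = None
    z2: np.ndarray | None = None
    log10p: np.ndarray | None = None
    hits: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")
        if np.any((self.maf < 0) | (self.maf > 0.5)):
            raise ValueError("MAF must be in [0, 0.5]")

    @property
    def n_variants(self) -> int:
        return self.alpha_hat.shape[0]

    @property
    def n_traits(self) -> int:
        return self.alpha_hat.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (variant, trait, beta, se, log10p, maf)."""
        n, t = self.alpha_hat.shape
        out = pd.DataFrame(
            {
                "variant": np.repeat(np.arange(n), t),
                "trait": np.tile(np.arange(t), n),
                "beta": self.alpha_hat.ravel(),
                "se": np.repeat(self.se, t),
                "maf": np.repeat(self.maf, t),
            }
        )
        if self.log10p is not None:
            out["log10p"] = self.log10p.ravel()
        if self.hits is not None:
            out["hit"] = self.hits.ravel()
        return out


def sample_gwas_frequency(
    pop_freq: float | np.ndarray,
    n_alleles: int = DEFAULT_N_ALLELES,
    seed: int | np.random.Generator = 0,
) -> float | np.ndarray:
    """Binomial sample allele frequency given the population frequency."""
    f = np.asarray(pop_freq, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("population frequency must be in [0, 1]")
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    rng = _as_rng(seed)
    out = rng.binomial(n_alleles, f) / n_alleles
    return float(out) if np.isscalar(pop_freq) else out


def simulate_gwas_estimates(
    effects: EffectMatrix,
    maf: np.ndarray,
    n_eff: float = DEFAULT_N_EFF,
    seed: int | np.random.Generator = 0,
    effect_mean: str = "signed_sqrt",
) -> GwasSummary:
    """Draw effect estimates normally distributed about their true values.

    The estimation noise has variance 1 / (2 n_eff maf (1 - maf)).  With
    ``effect_mean="signed_sqrt"`` the true per-trait effect is the signed
    square root of the squared effect (fair random sign per variant-trait;
    downstream statistics square the estimate, so the sign is immaterial)
    -- the convention in trait-SD-per-allele units.  With
    ``effect_mean="literal_squared"`` the estimate is centred on the
    squared-effect value itself; this is the hit-pleiotropy simulation's
    convention, under which the drawn positive vector plays the role of
    the effect size while its L1 norm plays the role of the selection
    strength.
    """
    maf = np.asarray(maf, dtype=float)
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("MAF must be strictly inside (0, 1): zero MAF gives infinite variance")
    rng = _as_rng(seed)
    sq = effects.sq_effects
    n, t = sq.shape
    if maf.shape != (n,):
        raise ValueError("maf must have one entry per position")
    se = 1.0 / np.sqrt(2.0 * n_eff * maf * (1.0 - maf))
    if effect_mean == "signed_sqrt":
        alpha = rng.choice([-1.0, 1.0], size=(n, t)) * np.sqrt(sq)
    elif effect_mean == "literal_squared":
        alpha = sq
    else:
        raise ValueError("effect_mean must be 'signed_sqrt' or 'literal_squared'")
    alpha_hat = alpha + rng.standard_normal((n, t)) * se[:, None]
    return GwasSummary(alpha_hat=alpha_hat, se=se, maf=np.minimum(maf, 1.0 - maf))


def pvalues_and_hits(summary: GwasSummary, threshold_t: float = DEFAULT_T) -> GwasSummary:
    """Fill in z^2, log10 P from the chi-squared(1) tail, and hit flags."""
    if not 0 < threshold_t <= 1:
        raise ValueError("threshold must be in (0, 1]")
    z2 = (summary.alpha_hat / summary.se[:, None]) ** 2
    log10p = log10_sf_chi2(z2)
    summary.z2 = z2
    summary.log10p = log10p
    summary.hits = log10p < np.log10(threshold_t)
    summary.threshold = threshold_t
    return summary


@dataclass
class BurdenSummary:
    """Per-gene x per-trait LoF burden-test summary statistics."""

    table: pd.DataFrame  # gene_id, p_lof, se, plus per-trait gamma_hat/z2/log10p
    n_traits: int
    untestable: list[str]

    def z2_matrix(self) -> np.ndarray:
        cols = [f"z2_{t}" for t in range(self.n_traits)]
        return self.table[cols].to_numpy()

    def gamma_hat_matrix(self) -> np.ndarray:
        cols = [f"gamma_hat_{t}" for t in range(self.n_traits)]
        return self.table[cols].to_numpy()


def _aggregate_carrier_freq(site_freqs: np.ndarray) -> float:
    """Probability a haplotype carries at least one LoF: 1 - prod(1 - p_i)."""
    return float(-np.expm1(np.log1p(-site_freqs).sum()))


def simulate_burden_test(
    gene: GeneModel,
    grid: SelectionGrid,
    n_samples: int = DEFAULT_BURDEN_N,
    freq_cap: float = DEFAULT_FREQ_CAP,
    seed: int | np.random.Generator = 0,
) -> dict | None:
    """Simulate one gene's burden summary; None if the gene is untestable.

    Per-site frequencies are drawn from the equilibrium spectrum nearest
    (log scale) to the gene's total trait effect; sites above ``freq_cap``
    are excluded from the burden genotype, mirroring the 1% site-frequency
    mask.  Returns a dict with p_lof, se and per-trait gamma_hat, z2,
    log10p.
    """
    rng = _as_rng(seed)
    if gene.n_sites < 1:
        return None
    sp = nearest_spectrum(grid, max(gene.s_het_gene, grid.grid[0]))
    counts = sp.sample_counts(gene.n_sites, rng)
    p = counts / sp.model.two_N
    p = p[(p > 0) & (p <= freq_cap)]
    if p.size == 0:
        return None
    p_lof = _aggregate_carrier_freq(p)
    if p_lof <= 0.0 or p_lof >= 1.0:
        return None
    se = 1.0 / np.sqrt(2.0 * n_samples * p_lof * (1.0 - p_lof))
    gamma = rng.choice([-1.0, 1.0], size=gene.gamma_sq.size) * np.sqrt(gene.gamma_sq)
    gamma_hat = gamma + rng.standard_normal(gamma.size) * se
    z2 = (gamma_hat / se) ** 2
    return {
        "gene_id": gene.gene_id,
        "p_lof": p_lof,
        "se": se,
        "n_sites_used": int(p.size),
        "gamma_hat": gamma_hat,
        "z2": z2,
        "log10p": log10_sf_chi2(z2),
    }


def simulate_burden_panel(
    genes: list[GeneModel],
    grid: SelectionGrid,
    n_samples: int = DEFAULT_BURDEN_N,
    freq_cap: float = DEFAULT_FREQ_CAP,
    seed: int | np.random.Generator = 0,
) -> BurdenSummary:
    """Vectorized burden simulation across a gene panel.

    Sites are drawn gene-by-gene grouped by nearest spectrum; genes whose
    included sites carry no LoF frequency are flagged untestable and
    omitted from the table.
    """
    rng = _as_rng(seed)
    if not genes:
        raise ValueError("empty gene panel")
    n_traits = genes[0].gamma_sq.size
    s_vals = np.array([max(g.s_het_gene, grid.grid[0]) for g in genes])
    idx = grid.nearest_indices(s_vals)
    n_sites = np.array([g.n_sites for g in genes])

    # draw all site frequencies grouped by spectrum, then split per gene
    p_lof = np.zeros(len(genes))
    sites_used = np.zeros(len(genes), dtype=int)
    order = np.argsort(idx, kind="stable")
    for k in np.unique(idx):
        sel = order[idx[order] == k]
        total = int(n_sites[sel].sum())
        sp = grid.spectra[k]
        freqs = sp.sample_counts(total, rng) / sp.model.two_N
        offs = np.concatenate([[0], np.cumsum(n_sites[sel])])
        for j, gi in enumerate(sel):
            p = freqs[offs[j] : offs[j + 1]]
            p = p[(p > 0) & (p <= freq_cap)]
            sites_used[gi] = p.size
            if p.size:
                p_lof[gi] = _aggregate_carrier_freq(p)

    testable = (p_lof > 0) & (p_lof < 1)
    untestable = [g.gene_id for g, ok in zip(genes, testable) if not ok]
    genes_ok = [g for g, ok in zip(genes, testable) if ok]
    p_ok = p_lof[testable]
    se = 1.0 / np.sqrt(2.0 * n_samples * p_ok * (1.0 - p_ok))
    gamma = np.array([g.gamma_sq for g in genes_ok])
    signs = rng.choice([-1.0, 1.0], size=gamma.shape)
    gamma_hat = signs * np.sqrt(gamma) + rng.standard_normal(gamma.shape) * se[:, None]
    z2 = (gamma_hat / se[:, None]) ** 2
    log10p = log10_sf_chi2(z2)

    data = {
        "gene_id": [g.gene_id for g in genes_ok],
        "p_lof": p_ok,
        "se": se,
        "n_sites_used": sites_used[testable],
    }
    for t in range(n_traits):
        data[f"gamma_hat_{t}"] = gamma_hat[:, t]
        data[f"z2_{t}"] = z2[:, t]
        data[f"log10p_{t}"] = log10p[:, t]
    return BurdenSummary(table=pd.DataFrame(data), n_traits=n_traits, untestable=untestable)


def subsample_summary(
    alpha_full: np.ndarray,
    se_full: np.ndarray,
    n_sub: float,
    n_full: float,
    seed: int | np.random.Generator = 0,
    se_mode: str = "sqrt",
) -> tuple[np.ndarray, np.ndarray]:
    """Summary statistics in a subsample, conditioned on the full sample.

    alpha_sub | alpha_full ~ Normal(alpha_full, ((N - n)/n) * SE^2), and
    standard errors grow by sqrt(N/n) (``se_mode="sqrt"``; the sampling
    variance of a mean scales as 1/n) or by N/n literally
    (``se_mode="literal"``).
    """
    if not 0 < n_sub <= n_full:
        raise ValueError("need 0 < n_sub <= n_full")
    alpha_full = np.asarray(alpha_full, dtype=float)
    se_full = np.asarray(se_full, dtype=float)
    rng = _as_rng(seed)
    ratio = (n_full - n_sub) / n_sub
    alpha_sub = alpha_full + rng.standard_normal(alpha_full.shape) * se_full * np.sqrt(ratio)
    if se_mode == "sqrt":
        se_sub = se_full * np.sqrt(n_full / n_sub)
    elif se_mode == "literal":
        se_sub = se_full * (n_full / n_sub)
    else:
        raise ValueError("se_mode must be 'sqrt' or 'literal'")
    if n_sub == n_full:
        alpha_sub = alpha_full.copy()
    return alpha_sub, se_sub


@dataclass
class RealizedHeritabilityTable:
    """Per-variant realized heritability 2 alpha^2 f(1-f), max-scaled."""

    s_het: np.ndarray
    pop_freq: np.ndarray
    sample_freq: np.ndarray
    scaled_sq_effect: np.ndarray
    scaled_realized_h2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_het": self.s_het,
                "pop_freq": self.pop_freq,
                "sample_freq": self.sample_freq,
                "scaled_sq_effect": self.scaled_sq_effect,
                "scaled_realized_h2": self.scaled_realized_h2,
            }
        )


def realized_heritability_experiment(
    grid: SelectionGrid,
    n_shet: int = 1000,
    shet_lo: float = 1e-7,
    shet_hi: float = 2.3e-4,
    variants_per_shet: int = 50,
    n_alleles: int = DEFAULT_N_ALLELES,
    seed: int | np.random.Generator = 0,
) -> RealizedHeritabilityTable:
    """Simulate unlinked variants and their realized heritability.

    s_het values are log-uniformly spaced; each contributes
    ``variants_per_shet`` variants whose population frequencies are drawn
    from the nearest equilibrium spectrum, then binomially resampled into
    a GWAS sample of ``n_alleles`` alleles.  All variants are equally
    trait specific, so the squared focal effect is proportional to s_het
    and the realized heritability is 2 s_het fs (1 - fs) up to a common
    constant; both axes are scaled by their maxima, which removes it.
    """
    rng = _as_rng(seed)
    s_vals = np.geomspace(shet_lo, shet_hi, n_shet)
    s_het = np.repeat(s_vals, variants_per_shet)
    idx = grid.nearest_indices(s_vals)
    pop = np.empty(s_het.size)
    for k in np.unique(idx):
        rows = np.where(idx == k)[0]
        sp = grid.spectra[k]
        block = sp.sample_counts(rows.size * variants_per_shet, rng) / sp.model.two_N
        for j, r in enumerate(rows):
            pop[r * variants_per_shet : (r + 1) * variants_per_shet] = block[
                j * variants_per_shet : (j + 1) * variants_per_shet
            ]
    fs = sample_gwas_frequency(pop, n_alleles=n_alleles, seed=rng)
    h2 = 2.0 * s_het * fs * (1.0 - fs)
    return RealizedHeritabilityTable(
        s_het=s_het,
        pop_freq=pop,
        sample_freq=fs,
        scaled_sq_effect=s_het / s_het.max(),
        scaled_realized_h2=h2 / h2.max() if h2.max() > 0 else h2,
    )
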