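"""Synthetic variants, genes and effect-size matrices with pleiotropy structure.

The generative model used throughout: the vector of squared effects of a
variant on T traits is drawn as

    alpha2 ~ (1e-7 / f) * exp{ 3 f * MVN(0, p*I + (1-p)*11') }

elementwise, where ``f`` controls the spread of total effect sizes and
``p`` the correlation structure (``p = 1`` gives independent traits,
``p = 0`` perfectly correlated ones).  The strength of selection against a
variant is the L1 norm of its squared-effect vector, and trait specificity
is the focal trait's share of that norm.  Genes carry an analogous vector
of squared LoF burden effects gamma_t^2 whose sum plays the role of s_het,
plus a mutational target size (expected number of unique LoF sites) that
is independent of effect sizes by construction.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .afs import DEFAULT_MU

__all__ = [
    "EffectMatrix",
    "GeneModel",
    "VariantOnGene",
    "TpmMatrix",
    "PeakMatrix",
    "draw_squared_effects",
    "selection_coefficient",
    "selection_coefficients",
    "trait_specificity",
    "trait_specificities",
    "make_gene_panel",
    "synth_specificity_matrices",
]

DEFAULT_N_TRAITS = 18
DEFAULT_F = 0.33
DEFAULT_P = 0.5
#: Focal study trait is always the first column.
FOCAL_TRAIT = 0


@dataclass(frozen=True)
class EffectMatrix:
    """Positions x traits matrix of squared per-trait effects."""

    sq_effects: np.ndarray
    f: float
    p: float

    def __post_init__(self) -> None:
        a = np.asarray(self.sq_effects, dtype=float)
        object.__setattr__(self, "sq_effects", a)
        if a.ndim != 2 or a.shape[1] < 1:
            raise ValueError("sq_effects must be 2-D with at least one trait")
        if np.any(a <= 0):
            raise ValueError("squared effects must be strictly positive")

    @property
    def n_positions(self) -> int:
        return self.sq_effects.shape[0]

    @property
    def n_traits(self) -> int:
        return self.sq_effects.shape[1]


def draw_squared_effects(
    n_positions: int,
    n_traits: int = DEFAULT_N_TRAITS,
    f: float = DEFAULT_F,
    p: float = DEFAULT_P,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EffectMatrix:
    """Draw squared effect-size vectors from the correlated log-normal model.

    Each row is (scale * 1e-7 / f) * exp(3 f * z) with
    z ~ MVN(0, p*I + (1-p)*11'), exponentiation elementwise.  The latent
    Gaussian is materialized as sqrt(p) * iid + sqrt(1-p) * shared, which
    realizes the stated covariance exactly.  Smaller ``f`` narrows the
    spread of total effect sizes while raising their overall scale;
    ``p = 1`` makes traits independent and ``p = 0`` perfectly correlated.
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if f <= 0:
        raise ValueError("f must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_iid = rng.standard_normal((n_positions, n_traits))
    z_shared = rng.standard_normal((n_positions, 1))
    z = np.sqrt(p) * z_iid + np.sqrt(1.0 - p) * z_shared
    sq = (scale * 1e-7 / f) * np.exp((3.0 * f) * z)
    return EffectMatrix(sq_effects=sq, f=f, p=p)


def selection_coefficient(sq_effect_row: np.ndarray) -> float:
    """Strength of selection against a variant: the L1 norm of its squared effects."""
    row = np.asarray(sq_effect_row, dtype=float)
    if np.any(row < 0):
        raise ValueError("squared effects must be nonnegative")
    return float(row.sum())


def selection_coefficients(effects: EffectMatrix | np.ndarray) -> np.ndarray:
    """Row-wise selection coefficients of an effect matrix."""
    a = effects.sq_effects if isinstance(effects, EffectMatrix) else np.asarray(effects)
    if np.any(a < 0):
        raise ValueError("squared effects must be nonnegative")
    return a.sum(axis=1)


def trait_specificity(sq_effect_row: np.ndarray, focal_index: int = FOCAL_TRAIT) -> float:
    """Trait specificity Psi: the focal trait's share of total importance."""
    row = np.asarray(sq_effect_row, dtype=float)
    total = selection_coefficient(row)
    if total <= 0:
        raise ValueError("trait specificity undefined for an all-zero effect vector")
    return float(row[focal_index] / total)


def trait_specificities(
    effects: EffectMatrix | np.ndarray, focal_index: int = FOCAL_TRAIT
) -> np.ndarray:
    """Row-wise Psi values."""
    a = effects.sq_effects if isinstance(effects, EffectMatrix) else np.asarray(effects)
    totals = selection_coefficients(a)
    if np.any(totals <= 0):
        raise ValueError("trait specificity undefined for an all-zero effect vector")
    return a[:, focal_index] / totals


@dataclass(frozen=True)
class GeneModel:
    """A gene with per-trait squared LoF effects and a mutational target size.

    ``s_het_gene`` is the sum of ``gamma_sq`` (total trait effect acts as
    the selection coefficient against LoF carriers); ``expected_lofs`` is
    the mu*L proxy (expected number of unique LoF sites) and ``n_sites``
    the implied number of potential LoF positions.
    """

    gene_id: str
    gamma_sq: np.ndarray
    expected_lofs: float
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma_sq, dtype=float)
        object.__setattr__(self, "gamma_sq", g)
        if np.any(g < 0):
            raise ValueError("gamma_sq entries must be nonnegative")
        if self.expected_lofs < 0:
            raise ValueError("expected_lofs must be >= 0")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")

    @property
    def s_het_gene(self) -> float:
        return float(self.gamma_sq.sum())

    @property
    def n_sites(self) -> int:
        return int(round(self.expected_lofs / DEFAULT_MU))

    @property
    def psi(self) -> float:
        return trait_specificity(self.gamma_sq)


@dataclass(frozen=True)
class VariantOnGene:
    """A cis variant with squared effect beta^2 on its gene.

    The variant's squared trait effects are beta^2 * gamma_t^2.
    """

    variant_id: str
    gene_id: str
    beta_sq: float
    gamma_sq: np.ndarray

    @property
    def alpha_sq(self) -> np.ndarray:
        return self.beta_sq * np.asarray(self.gamma_sq, dtype=float)


def _psi_targets(
    n_genes: int,
    specificity_mix: float | tuple | None,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Target focal-trait shares under the requested specificity mix.

    ``None`` keeps the shares the correlated log-normal draw produced;
    a float plants that share for every gene; ``("beta", a, b)`` draws
    shares from a Beta(a, b) distribution.
    """
    if specificity_mix is None:
        return None
    if isinstance(specificity_mix, tuple):
        kind, a, b = specificity_mix
        if kind != "beta":
            raise ValueError(f"unknown specificity_mix kind {kind!r}")
        return rng.beta(a, b, size=n_genes)
    psi = float(specificity_mix)
    if not 0.0 < psi <= 1.0:
        raise ValueError("fixed specificity must be in (0, 1]")
    return np.full(n_genes, psi)


def make_gene_panel(
    n_genes: int = 18_400,
    n_traits: int = DEFAULT_N_TRAITS,
    shet_range: tuple[float, float] = (1e-4, 0.05),
    lof_length_range: tuple[float, float] = (6.25e-7, 6.25e-5),
    specificity_mix: float | tuple | None = ("beta", 0.5, 2.0),
    genome_layout: dict | None = None,
    variants_per_gene: int = 0,
    beta_sdlog: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[GeneModel], list[VariantOnGene]]:
    """Synthesize a gene panel (and optionally cis variants).

    Gene gamma^2 vectors are drawn with the same correlated log-normal
    machinery as variant effects and rescaled so that the total trait
    effect sum(gamma^2) is log-uniform over ``shet_range``.  The mu*L
    proxy (``expected_lofs``) is log-uniform over ``lof_length_range``
    independently of effect sizes, so mutational target size and trait
    importance are uncorrelated by construction.  ``specificity_mix``
    optionally re-plants the focal-trait share (see ``_psi_targets``).
    Cis variant squared effects beta^2 are log-normal with median 1 and
    log-sd ``beta_sdlog`` (a free modelling choice; the analyses only use
    relative beta).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = shet_range
    if not 0 < lo < hi:
        raise ValueError("invalid shet_range")
    llo, lhi = lof_length_range
    if not 0 < llo < lhi:
        raise ValueError("invalid lof_length_range")
    layout = {"n_chroms": 22, "spacing": 100_000, "bp_per_site": 3}
    if genome_layout:
        layout.update(genome_layout)

    shape = draw_squared_effects(n_genes, n_traits, seed=rng).sq_effects
    totals = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    gamma_sq = shape / shape.sum(axis=1, keepdims=True) * totals[:, None]

    psi_t = _psi_targets(n_genes, specificity_mix, rng)
    if psi_t is not None:
        rest = gamma_sq[:, 1:].sum(axis=1)
        gamma_sq[:, 0] = psi_t * totals
        with np.errstate(invalid="ignore", divide="ignore"):
            scale_rest = np.where(rest > 0, (1.0 - psi_t) * totals / rest, 0.0)
        gamma_sq[:, 1:] *= scale_rest[:, None]

    expected_lofs = np.exp(rng.uniform(np.log(llo), np.log(lhi), size=n_genes))
    n_sites = np.maximum(1, np.round(expected_lofs / DEFAULT_MU)).astype(int)

    genes: list[GeneModel] = []
    per_chrom_cursor = dict.fromkeys(range(layout["n_chroms"]), 0)
    for i in range(n_genes):
        c = i % layout["n_chroms"]
        start = per_chrom_cursor[c]
        length = int(n_sites[i]) * layout["bp_per_site"]
        end = start + max(length, 1)
        per_chrom_cursor[c] = end + layout["spacing"]
        genes.append(
            GeneModel(
                gene_id=f"G{i:06d}",
                gamma_sq=gamma_sq[i],
                expected_lofs=float(expected_lofs[i]),
                chrom=f"chr{c + 1}",
                start=start,
                end=end,
            )
        )

    variants: list[VariantOnGene] = []
    if variants_per_gene > 0:
        beta_sq = np.exp(rng.normal(0.0, beta_sdlog, size=(n_genes, variants_per_gene))) ** 2
        for i, g in enumerate(genes):
            for j in range(variants_per_gene):
                variants.append(
                    VariantOnGene(
                        variant_id=f"{g.gene_id}.v{j}",
                        gene_id=g.gene_id,
                        beta_sq=float(beta_sq[i, j]),
                        gamma_sq=g.gamma_sq,
                    )
                )
    return genes, variants


@dataclass(frozen=True)
class TpmMatrix:
    """Genes x tissues expression matrix in TPM with a focal tissue."""

    values: np.ndarray
    gene_ids: list[str]
    tissues: list[str]
    focal_tissue: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least 2 tissues")
        if np.any(v < 0):
            raise ValueError("TPM values must be nonnegative")
        if self.focal_tissue not in self.tissues:
            raise ValueError(f"focal tissue {self.focal_tissue!r} not in matrix")

    @property
    def focal_index(self) -> int:
        return self.tissues.index(self.focal_tissue)


@dataclass(frozen=True)
class PeakMatrix:
    """Peaks x tissues presence-fraction matrix with a focal tissue."""

    values: np.ndarray
    peak_ids: list[str]
    tissues: list[str]
    focal_tissue: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least 2 tissues")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("presence fractions must be in [0, 1]")
        if self.focal_tissue not in self.tissues:
            raise ValueError(f"focal tissue {self.focal_tissue!r} not in matrix")

    @property
    def focal_index(self) -> int:
        return self.tissues.index(self.focal_tissue)


def synth_specificity_matrices(
    n_genes: int = 500,
    n_tissues: int = 17,
    n_peak_tissues: int = 19,
    planted_bins: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[TpmMatrix, PeakMatrix]:
    """Synthetic TPM and ATAC-presence matrices with known planted structure.

    ``planted_bins`` assigns each gene a quintile 1-5 (or 0 for "not
    expressed in the focal tissue").  Genes in higher quintiles receive
    higher focal-tissue expression shares; the matching peak matrix plants
    sharing counts so that quintile-5 peaks are focal-specific.  Useful for
    round-trip tests of the specificity scorers.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if planted_bins is None:
        planted_bins = rng.integers(0, 6, size=n_genes)
    planted_bins = np.asarray(planted_bins)
    if planted_bins.shape != (n_genes,):
        raise ValueError("planted_bins must have one entry per gene")
    if planted_bins.min() < 0 or planted_bins.max() > 5:
        raise ValueError("planted_bins entries must be in 0..5")

    tissues = [f"tissue_{string.ascii_lowercase[i % 26]}{i // 26}" for i in range(n_tissues)]
    focal = tissues[0]
    # disjoint specificity-score ranges per quintile so pooled quantile
    # binning recovers the planted labels exactly
    score_lo = np.array([np.nan, 0.10, 0.26, 0.42, 0.58, 0.74])
    tpm = np.zeros((n_genes, n_tissues))
    focal_tpm = 50.0
    for i, b in enumerate(planted_bins):
        if b == 0:
            tpm[i, 0] = rng.uniform(0.0, 9.0)  # below the "expressed" threshold
            tpm[i, 1:] = rng.uniform(1.0, 20.0, size=n_tissues - 1)
            continue
        psi = score_lo[b] + rng.uniform(0.01, 0.14)
        tpm[i, 0] = focal_tpm
        other_total = focal_tpm * (1.0 - psi) / psi
        w = rng.dirichlet(np.ones(n_tissues - 1))
        tpm[i, 1:] = other_total * w
    gene_ids = [f"G{i:06d}" for i in range(n_genes)]
    tpm_mat = TpmMatrix(values=tpm, gene_ids=gene_ids, tissues=tissues, focal_tissue=focal)

    peak_tissues = [f"ptissue_{i}" for i in range(n_peak_tissues)]
    # sharing count per quintile: most specific quintile -> fewest tissues
    share_by_bin = {1: n_peak_tissues, 2: 16, 3: 9, 4: 3, 5: 1}
    present_frac, absent_frac = 0.5, 0.01
    peaks = np.full((n_genes, n_peak_tissues), absent_frac)
    for i, b in enumerate(planted_bins):
        if b == 0:
            peaks[i, :] = absent_frac  # absent from focal tissue
            continue
        k = min(share_by_bin[b], n_peak_tissues)
        peaks[i, :k] = present_frac
    peak_ids = [f"P{i:06d}" for i in range(n_genes)]
    peak_mat = PeakMatrix(
        values=peaks, peak_ids=peak_ids, tissues=peak_tissues, focal_tissue=peak_tissues[0]
    )
    return tpm_mat, peak_mat
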