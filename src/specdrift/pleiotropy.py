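"""Apparent pleiotropy of GWAS hits, quartiled by significance.

Genetic drift spreads allele frequencies widely around their selection-
determined expectations, and statistical power rises steeply with minor
allele frequency.  Among genome-wide significant hits for a focal trait,
the most significant quartile is therefore enriched for variants that
drifted to high frequency -- which are simultaneously more likely to be
significant for *other* traits (more apparently pleiotropic) and, on
average, more trait specific in their true effects.  This module
reproduces that pattern from simulated (or user-supplied) hit tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afs import SelectionGrid, default_selection_grid
from .assoc import DEFAULT_N_EFF, DEFAULT_T, pvalues_and_hits, simulate_gwas_estimates
from .effects import (
    DEFAULT_F,
    DEFAULT_N_TRAITS,
    DEFAULT_P,
    draw_squared_effects,
    selection_coefficients,
)

__all__ = ["PleiotropyParams", "quartile_pleiotropy_profile", "run_pleiotropy_simulation"]

MIN_HITS_PER_TRAIT = 100


@dataclass(frozen=True)
class PleiotropyParams:
    """Parameters of the hit-pleiotropy simulation (defaults follow the study)."""

    n_positions: int = 1_000_000
    n_traits: int = DEFAULT_N_TRAITS
    f: float = DEFAULT_F
    p: float = DEFAULT_P
    n_eff: float = DEFAULT_N_EFF
    threshold_t: float = DEFAULT_T
    # Real-data analyses keep only traits with at least 100 hits; at the
    # desk-scale position count each simulated trait lands near 10-40
    # hits, so the simulation profiles all traits with a lower floor and
    # the quartile contrasts aggregate across the 18 traits.
    min_hits_per_trait: int = 10
    # Variants whose total effect exceeds the strongest computed spectrum:
    # "clip" samples their frequency from that spectrum, "drop" treats
    # them as effectively never segregating.
    beyond_grid: str = "clip"


def quartile_pleiotropy_profile(
    hit_log10p: np.ndarray,
    hit_maf: np.ndarray,
    hit_traits_count: np.ndarray,
    trait_labels: np.ndarray,
    hit_psi: np.ndarray | None = None,
    min_hits: int = MIN_HITS_PER_TRAIT,
) -> pd.DataFrame:
    """Quartile profiles of hits, per trait.

    Inputs are parallel arrays over (variant, trait) hit records:
    ``hit_log10p`` the hit's significance for its focal trait,
    ``hit_maf`` its MAF, ``hit_traits_count`` the number of traits for
    which the variant is a hit (including the focal one), ``trait_labels``
    the focal trait of each record, and optionally ``hit_psi`` the true
    trait specificity.  Traits with fewer than ``min_hits`` hits are
    excluded.  Quartile 1 contains the most significant hits; quartile
    MAF means are reported relative to the trait's overall hit MAF mean.
    """
    out = []
    for t in np.unique(trait_labels):
        sel = trait_labels == t
        if sel.sum() < max(min_hits, 4):  # need at least one hit per quartile
            continue
        lp = hit_log10p[sel]
        maf = hit_maf[sel]
        cnt = hit_traits_count[sel]
        psi = hit_psi[sel] if hit_psi is not None else None
        order = np.lexsort((maf, lp))  # ascending log10p = most significant first
        overall_maf = maf.mean()
        for q, rows in enumerate(np.array_split(order, 4), start=1):
            rec = {
                "trait": t,
                "quartile": q,
                "rel_maf": maf[rows].mean() / overall_maf,
                "mean_traits_hit": cnt[rows].mean(),
                "n": rows.size,
            }
            rec["mean_psi"] = psi[rows].mean() if psi is not None else np.nan
            out.append(rec)
    return pd.DataFrame(out)


def run_pleiotropy_simulation(
    params: PleiotropyParams = PleiotropyParams(),
    seed: int | np.random.Generator = 0,
    grid: SelectionGrid | None = None,
) -> dict:
    """End-to-end hit-pleiotropy simulation.

    Chain: draw squared-effect vectors -> total effect = selection
    strength -> population frequency from the nearest equilibrium
    spectrum -> GWAS estimates with frequency-dependent noise -> P values
    and hit flags -> quartile profiles.  Positions drawn monomorphic never
    become hits and are excluded from the association step.

    Returns a dict with the per-trait hit tables, the quartile profiles,
    true specificities of segregating variants, and the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if grid is None:
        grid = default_selection_grid()
    eff = draw_squared_effects(
        params.n_positions, params.n_traits, params.f, params.p, seed=rng
    )
    s_raw = selection_coefficients(eff)
    s = np.clip(s_raw, grid.grid[0], grid.grid[-1])
    idx = grid.nearest_indices(s)
    freq = np.empty(params.n_positions)
    for k in np.unique(idx):
        rows = np.where(idx == k)[0]
        sp = grid.spectra[k]
        freq[rows] = sp.sample_counts(rows.size, rng) / sp.model.two_N
    if params.beyond_grid == "drop":
        freq[s_raw > grid.grid[-1]] = 0.0
    elif params.beyond_grid != "clip":
        raise ValueError("beyond_grid must be 'clip' or 'drop'")
    segregating = (freq > 0) & (freq < 1)
    from .effects import EffectMatrix

    eff_seg = EffectMatrix(eff.sq_effects[segregating], eff.f, eff.p)
    maf = np.minimum(freq[segregating], 1.0 - freq[segregating])
    summary = simulate_gwas_estimates(eff_seg, maf, n_eff=params.n_eff, seed=rng)
    summary = pvalues_and_hits(summary, threshold_t=params.threshold_t)
    # per-trait specificity: each trait is analysed as its own study trait,
    # so a hit on trait t carries Psi_t = alpha_t^2 / sum_k alpha_k^2
    psi_matrix = eff_seg.sq_effects / eff_seg.sq_effects.sum(axis=1, keepdims=True)

    hits = summary.hits
    traits_count = hits.sum(axis=1)
    hit_tables = {}
    rec_lp, rec_maf, rec_cnt, rec_trait, rec_psi = [], [], [], [], []
    for t in range(params.n_traits):
        rows = np.where(hits[:, t])[0]
        hit_tables[t] = pd.DataFrame(
            {
                "variant": rows,
                "log10p": summary.log10p[rows, t],
                "maf": summary.maf[rows],
                "traits_hit": traits_count[rows],
                "psi": psi_matrix[rows, t],
            }
        )
        rec_lp.append(summary.log10p[rows, t])
        rec_maf.append(summary.maf[rows])
        rec_cnt.append(traits_count[rows])
        rec_trait.append(np.full(rows.size, t))
        rec_psi.append(psi_matrix[rows, t])
    profiles = quartile_pleiotropy_profile(
        np.concatenate(rec_lp),
        np.concatenate(rec_maf),
        np.concatenate(rec_cnt).astype(float),
        np.concatenate(rec_trait),
        np.concatenate(rec_psi),
        min_hits=params.min_hits_per_trait,
    )
    if profiles.empty:
        import warnings

        warnings.warn("no trait reached the minimum hit count; empty profile")
    return {
        "hit_tables": hit_tables,
        "profiles": profiles,
        "n_segregating": int(segregating.sum()),
        "seed": seed if isinstance(seed, int) else None,
        "params": params,
    }
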