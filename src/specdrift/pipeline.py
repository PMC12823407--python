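"""Run configuration, seeded stage orchestration, and manifests.

Every stage derives its own random stream from the master seed keyed by
the stage name (via ``SeedSequence`` spawn keys), so adding or reordering
stages does not perturb the draws of the others, and identical
config + seed reproduces outputs byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .afs import DEFAULT_MU, SelectionGrid, default_selection_grid
from .assoc import realized_heritability_experiment
from .estimators import flattening_analysis
from .io import write_summary_tsv
from .pleiotropy import PleiotropyParams, run_pleiotropy_simulation

__all__ = ["RunConfig", "stage_rng", "run_pipeline", "STAGES"]


@dataclass
class RunConfig:
    """Pipeline configuration with study-default parameters."""

    stages: list[str] = field(default_factory=lambda: ["pleiotropy-sim"])
    seed: int = 0
    out_prefix: str = "specdrift_run"
    # association thresholds
    gwas_threshold: float = 5e-8
    burden_threshold: float = 2.7e-6
    window_bp: int = 1_000_000
    n_alleles: int = 600_000
    # pleiotropy simulation
    f: float = 0.33
    p: float = 0.5
    n_eff: float = 1e7
    t: float = 1e-5
    n_positions: int = 1_000_000
    n_traits: int = 18
    # population genetics
    mu: float = DEFAULT_MU
    grid_min: float = 1e-7
    grid_max: float = 0.05
    grid_size: int = 50
    grid_two_n: int = 2_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator keyed by the stage name."""
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


def _grid(config: RunConfig) -> SelectionGrid:
    return default_selection_grid(
        grid_min=config.grid_min,
        grid_max=config.grid_max,
        grid_size=config.grid_size,
        mu=config.mu,
        two_N=config.grid_two_n,
    )


def _stage_afs(config: RunConfig, rng, outdir: Path) -> dict:
    grid = _grid(config)
    summary = [
        (s, sp.model.two_N, sp.mean_frequency(), sp.mean_heterozygosity())
        for s, sp in zip(grid.grid, grid.spectra)
    ]
    np.savetxt(
        outdir / f"{config.out_prefix}.grid.tsv",
        np.array(summary),
        delimiter="\t",
        header="s_het\ttwo_N\tmean_freq\tmean_het",
    )
    # spectra may live on different count grids (adaptive sizing), so each
    # line carries its own s_het, two_N and probability vector
    with open(outdir / f"{config.out_prefix}.spectra.tsv", "w") as fh:
        for s, sp in zip(grid.grid, grid.spectra):
            probs = "\t".join(f"{x:.10e}" for x in sp.probs)
            fh.write(f"{s:.6e}\t{sp.model.two_N}\t{probs}\n")
    return {
        "grid_size": len(grid.grid),
        "mean_freq_min": float(grid.mean_frequencies().min()),
        "mean_freq_max": float(grid.mean_frequencies().max()),
    }


def _stage_pleiotropy(config: RunConfig, rng, outdir: Path) -> dict:
    params = PleiotropyParams(
        n_positions=config.n_positions,
        n_traits=config.n_traits,
        f=config.f,
        p=config.p,
        n_eff=config.n_eff,
        threshold_t=config.t,
    )
    res = run_pleiotropy_simulation(params, seed=rng, grid=_grid(config))
    write_summary_tsv(res["profiles"], outdir / f"{config.out_prefix}.pleiotropy_profiles.tsv")
    return {
        "n_segregating": res["n_segregating"],
        "n_profiled_traits": int(res["profiles"]["trait"].nunique()) if len(res["profiles"]) else 0,
    }


def _stage_realized_h2(config: RunConfig, rng, outdir: Path) -> dict:
    tab = realized_heritability_experiment(_grid(config), n_alleles=config.n_alleles, seed=rng)
    write_summary_tsv(tab.to_frame(), outdir / f"{config.out_prefix}.realized_h2.tsv")
    return {"n_variants": int(tab.s_het.size)}


def _stage_flattening(config: RunConfig, rng, outdir: Path) -> dict:
    gamma = np.geomspace(1e-3, 2e-2, 12)
    res = flattening_analysis(gamma, seed=rng)
    df = {
        "gene_gamma": res.gene_gamma,
        "gene_total": res.gene_total,
    }
    import pandas as pd

    write_summary_tsv(pd.DataFrame(df), outdir / f"{config.out_prefix}.flattening_genes.tsv")
    return {"n_genes": int(res.gene_gamma.size)}


STAGES = {
    "afs": _stage_afs,
    "pleiotropy-sim": _stage_pleiotropy,
    "realized-h2": _stage_realized_h2,
    "flattening": _stage_flattening,
}


def run_pipeline(config: RunConfig, outdir: str | Path = ".") -> dict:
    """Execute the configured stage chain; returns and writes the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; available: {sorted(STAGES)}")
        rng = stage_rng(config.seed, stage)
        manifest["stages"][stage] = STAGES[stage](config, rng, outdir)
    with open(outdir / f"{config.out_prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
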