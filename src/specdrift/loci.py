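"""GWAS locus grouping, ranking, power matching and burden concordance.

Hits are rows of a DataFrame with columns (chrom, pos, log10p, beta, maf);
coordinates are 0-based and intervals half-open throughout.  Loci are
built by iterating hits from most to least significant: the most
significant unassigned hit seeds a locus, every unassigned hit within the
window joins, and the expansion is repeated to a fixed point so that no
unassigned hit remains within the window of any member.  The locus span is
the member range padded by half the window on each side (clipped at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "group_hits_into_loci",
    "assign_genes",
    "rank_loci",
    "select_power_matched_top_loci",
    "burden_gwas_overlap",
    "ld_block_compare",
    "filter_hits_by_maf",
    "GWAS_SIG_LOG10P",
    "BURDEN_SIG_LOG10P",
]

DEFAULT_WINDOW_BP = 1_000_000
#: Genome-wide significance for GWAS (P < 5e-8), in log10.
GWAS_SIG_LOG10P = float(np.log10(5e-8))
#: Per-trait burden-test significance (P < 2.7e-6), in log10.
BURDEN_SIG_LOG10P = float(np.log10(2.7e-6))

HIT_COLUMNS = ("chrom", "pos", "log10p")


@dataclass
class Locus:
    """A ranked genomic interval with member hits and overlapping genes."""

    chrom: str
    start: int
    end: int
    hit_rows: pd.DataFrame
    min_log10p: float
    genes: list[str] = field(default_factory=list)
    rank: int | None = None

    @property
    def n_hits(self) -> int:
        return len(self.hit_rows)


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    for c in HIT_COLUMNS:
        if c not in hits.columns:
            raise ValueError(f"hits table missing required column {c!r}")
    if hits.duplicated(subset=["chrom", "pos"]).any():
        dup = hits[hits.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise ValueError(f"duplicate hit at {dup['chrom']}:{dup['pos']}")
    if (hits["log10p"] > 0).any():
        raise ValueError("log10p must be <= 0")
    if (hits["pos"] < 0).any():
        raise ValueError("positions must be >= 0")
    return hits


def group_hits_into_loci(
    hits: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    span_pad: int | None = None,
) -> list[Locus]:
    """Group LD-clumped hits into non-overlapping loci (see module docstring).

    ``span_pad`` controls the padding added to the member range for the
    reported span and gene assignment; it defaults to ``window_bp // 2``.
    """
    if span_pad is None:
        span_pad = window_bp // 2
    if len(hits) == 0:
        return []
    hits = _validate_hits(hits.reset_index(drop=True))
    loci: list[Locus] = []
    for chrom, sub in hits.groupby("chrom", sort=True):
        sub = sub.sort_values(["log10p", "pos"], kind="mergesort")
        pos = sub["pos"].to_numpy()
        unassigned = np.ones(len(sub), dtype=bool)
        for i in range(len(sub)):
            if not unassigned[i]:
                continue
            member = np.zeros(len(sub), dtype=bool)
            member[i] = True
            unassigned[i] = False
            # expand to a fixed point: add any unassigned hit within the
            # window of any current member
            while True:
                cand = np.where(unassigned)[0]
                if cand.size == 0:
                    break
                mem_pos = pos[member]
                near = np.abs(pos[cand][:, None] - mem_pos[None, :]).min(axis=1) <= window_bp
                if not near.any():
                    break
                newly = cand[near]
                member[newly] = True
                unassigned[newly] = False
            rows = sub[member]
            lo = int(rows["pos"].min())
            hi = int(rows["pos"].max())
            loci.append(
                Locus(
                    chrom=str(chrom),
                    start=max(0, lo - span_pad),
                    end=hi + span_pad + 1,
                    hit_rows=rows.copy(),
                    min_log10p=float(rows["log10p"].min()),
                )
            )
    return loci


def assign_genes(loci: list[Locus], genes: pd.DataFrame) -> list[Locus]:
    """Attach overlapping gene ids to each locus (half-open intervals)."""
    for c in ("gene_id", "chrom", "start", "end"):
        if c not in genes.columns:
            raise ValueError(f"gene table missing required column {c!r}")
    if (genes["start"] >= genes["end"]).any():
        raise ValueError("malformed gene interval: start must be < end")
    by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    for loc in loci:
        sub = by_chrom.get(loc.chrom)
        if sub is None:
            loc.genes = []
            continue
        ov = (sub["start"] < loc.end) & (sub["end"] > loc.start)
        loc.genes = sub.loc[ov, "gene_id"].tolist()
    return loci


def rank_loci(
    loci: list[Locus],
    mode: str = "min_p",
    sig_log10p: float = GWAS_SIG_LOG10P,
) -> list[Locus]:
    """Rank loci by minimum P value or by largest significant |effect|.

    In ``max_abs_beta_significant`` mode a locus with no genome-wide
    significant member carrying an effect estimate is excluded.  Ties are
    broken by (chrom, span start); ranks are 1-based.
    """
    if mode == "min_p":
        keyed = [((loc.min_log10p, loc.chrom, loc.start), loc) for loc in loci]
    elif mode == "max_abs_beta_significant":
        keyed = []
        for loc in loci:
            sig = loc.hit_rows[loc.hit_rows["log10p"] < sig_log10p]
            if len(sig) == 0 or "beta" not in sig.columns:
                continue
            keyed.append(((-sig["beta"].abs().max(), loc.chrom, loc.start), loc))
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    keyed.sort(key=lambda kv: kv[0])
    ranked = []
    for r, (_, loc) in enumerate(keyed, start=1):
        loc.rank = r
        ranked.append(loc)
    return ranked


def select_power_matched_top_loci(
    ranked_loci: list[Locus],
    burden: pd.DataFrame,
    burden_sig_log10p: float = BURDEN_SIG_LOG10P,
) -> tuple[list[Locus], list[str]]:
    """Top GWAS loci matched to the burden test's discovery count.

    The target is the number of burden-significant genes.  Walking loci in
    rank order, each locus contributes all of its burden-significant
    member genes, or failing that its single member gene with the smallest
    burden P value; the walk stops once at least the target number of
    genes has been selected.
    """
    for c in ("gene_id", "log10p"):
        if c not in burden.columns:
            raise ValueError(f"burden table missing required column {c!r}")
    btab = burden.set_index("gene_id")["log10p"]
    target = int((btab < burden_sig_log10p).sum())
    if target == 0:
        return [], []
    selected_loci: list[Locus] = []
    selected_genes: list[str] = []
    seen = set()
    for loc in ranked_loci:
        members = [g for g in loc.genes if g not in seen]
        if not members:
            continue
        with_p = [(btab.get(g, 0.0), g) for g in members]
        sig = [g for p, g in with_p if p < burden_sig_log10p]
        take = sig if sig else [min(with_p)[1]]
        selected_loci.append(loc)
        for g in take:
            seen.add(g)
            selected_genes.append(g)
        if len(selected_genes) >= target:
            break
    return selected_loci, selected_genes


def burden_gwas_overlap(
    burden_genes: list[str],
    loci: list[Locus],
    top_loci: list[Locus] | None = None,
) -> dict:
    """Concordance between burden-significant genes and GWAS loci.

    Returns the fraction of burden genes contained in any locus, the
    fraction contained in the power-matched top loci, and a rank-pairing
    table (burden rank order preserved; locus rank or None).
    """
    all_genes: dict[str, int | None] = {}
    for loc in loci:
        for g in loc.genes:
            cur = all_genes.get(g)
            if g not in all_genes or (loc.rank is not None and (cur is None or loc.rank < cur)):
                all_genes[g] = loc.rank
    top_genes = set()
    for loc in top_loci or []:
        top_genes.update(loc.genes)
    n = len(burden_genes)
    in_any = sum(g in all_genes for g in burden_genes)
    in_top = sum(g in top_genes for g in burden_genes)
    pairing = pd.DataFrame(
        {
            "gene_id": burden_genes,
            "burden_rank": np.arange(1, n + 1),
            "locus_rank": [all_genes.get(g) for g in burden_genes],
        }
    )
    return {
        "fraction_in_any_locus": in_any / n if n else float("nan"),
        "fraction_in_top_loci": in_top / n if n else float("nan"),
        "rank_pairs": pairing,
    }


def ld_block_compare(
    blocks: pd.DataFrame,
    gwas_hits: pd.DataFrame,
    burden: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Minimum GWAS and burden P values per approximately independent LD block.

    A block overlapping no hits or genes gets NaN minima.  Any block whose
    minimizing burden gene also minimizes another block is flagged dropped
    (one highly significant gene spanning two blocks would otherwise
    manufacture concordance).
    """
    for c in ("chrom", "start", "end"):
        if c not in blocks.columns:
            raise ValueError(f"block table missing required column {c!r}")
    for c, sub in blocks.groupby("chrom"):
        iv = sub.sort_values("start")
        if (iv["start"].to_numpy()[1:] < iv["end"].to_numpy()[:-1]).any():
            raise ValueError(f"blocks overlap on {c}")
    btab = burden.set_index("gene_id")["log10p"]
    records = []
    for _, blk in blocks.iterrows():
        in_blk = gwas_hits[
            (gwas_hits["chrom"] == blk["chrom"])
            & (gwas_hits["pos"] >= blk["start"])
            & (gwas_hits["pos"] < blk["end"])
        ]
        min_gwas = float(in_blk["log10p"].min()) if len(in_blk) else np.nan
        ov = genes[
            (genes["chrom"] == blk["chrom"])
            & (genes["start"] < blk["end"])
            & (genes["end"] > blk["start"])
        ]
        gene_ps = btab.reindex(ov["gene_id"]).dropna()
        if len(gene_ps):
            min_burden = float(gene_ps.min())
            min_gene = gene_ps.idxmin()
        else:
            min_burden, min_gene = np.nan, None
        records.append(
            {
                "chrom": blk["chrom"],
                "start": int(blk["start"]),
                "end": int(blk["end"]),
                "min_gwas_log10p": min_gwas,
                "min_burden_log10p": min_burden,
                "min_burden_gene": min_gene,
            }
        )
    out = pd.DataFrame(records)
    counts = out["min_burden_gene"].value_counts()
    shared = set(counts[counts > 1].index)
    out["dropped"] = out["min_burden_gene"].isin(shared)
    return out


def filter_hits_by_maf(hits: pd.DataFrame, maf_threshold: float) -> pd.DataFrame:
    """Keep hits with MAF at or below the threshold (inclusive)."""
    if not 0 < maf_threshold <= 0.5:
        raise ValueError("MAF threshold must be in (0, 0.5]")
    if "maf" not in hits.columns:
        raise ValueError("hits table missing required column 'maf'")
    return hits[hits["maf"] <= maf_threshold].copy()
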