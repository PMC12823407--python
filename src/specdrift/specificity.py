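"""Expression- and chromatin-based proxies for trait specificity.

A gene expressed almost exclusively in a trait's causal tissue is a
plausible trait-specific gene; an ATAC peak open in few tissues marks a
context-specific regulatory element.  These scores are the observable
stand-ins for the (unobservable) true specificity Psi used by the theory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import PeakMatrix, TpmMatrix

__all__ = [
    "expression_specificity_scores",
    "pooled_quintiles",
    "atac_peak_specificity",
    "SHARING_BIN_EDGES",
]

TPM_EXPRESSED_THRESHOLD = 10.0
PRESENCE_THRESHOLD = 0.05
#: Tissue-sharing bins: (label, inclusive lo, inclusive hi).
SHARING_BIN_EDGES = [
    ("1-2", 1, 2),
    ("3-8", 3, 8),
    ("9-15", 9, 15),
    ("16-18", 16, 18),
    ("19", 19, 19),
]


def expression_specificity_scores(
    tpm: TpmMatrix,
    tpm_threshold: float = TPM_EXPRESSED_THRESHOLD,
) -> pd.DataFrame:
    """Focal-tissue expression specificity per gene.

    A gene is "expressed" when its focal-tissue TPM strictly exceeds the
    threshold; its score is the focal TPM divided by the sum across all
    tissues (focal included).  Unexpressed genes carry NaN scores and are
    excluded from downstream binning.
    """
    fi = tpm.focal_index
    focal = tpm.values[:, fi]
    expressed = focal > tpm_threshold
    row_sum = tpm.values.sum(axis=1)
    score = np.full(len(tpm.gene_ids), np.nan)
    score[expressed] = focal[expressed] / row_sum[expressed]
    return pd.DataFrame(
        {
            "id": tpm.gene_ids,
            "focal_tissue": tpm.focal_tissue,
            "expressed": expressed,
            "score": score,
        }
    )


def pooled_quintiles(profiles: list[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Assign quintile bins from the score distribution pooled across pairs.

    Breakpoints are the 20/40/60/80% quantiles of all flagged entities'
    scores pooled across the supplied trait-tissue profiles; each entity
    gets the quintile of its own score, with ties at a breakpoint going to
    the lower bin.  Bin 5 is the most specific.
    """
    if isinstance(profiles, pd.DataFrame):
        profiles = [profiles]
    pooled = pd.concat(profiles, ignore_index=True)
    flagged = pooled[pooled["expressed"]] if "expressed" in pooled else pooled.dropna(
        subset=["score"]
    )
    scores = flagged["score"].dropna().to_numpy()
    if scores.size < 5:
        raise ValueError("need at least 5 flagged entities to form quintiles")
    breaks = np.quantile(scores, [0.2, 0.4, 0.6, 0.8])
    out = []
    for prof in profiles:
        prof = prof.copy()
        b = np.where(
            prof["score"].notna() & prof.get("expressed", True),
            1 + (prof["score"].to_numpy()[:, None] > breaks[None, :]).sum(axis=1),
            0,
        )
        prof["bin"] = pd.array(b, dtype="Int64")
        prof.loc[prof["bin"] == 0, "bin"] = pd.NA
        out.append(prof)
    return pd.concat(out, ignore_index=True) if len(out) > 1 else out[0]


def _sharing_bin(counts: np.ndarray) -> np.ndarray:
    labels = np.empty(counts.size, dtype=object)
    for lab, lo, hi in SHARING_BIN_EDGES:
        labels[(counts >= lo) & (counts <= hi)] = lab
    # sharing beyond the labelled range (more tissues than the reference 19)
    labels[counts > SHARING_BIN_EDGES[-1][2]] = SHARING_BIN_EDGES[-1][0]
    return labels


def atac_peak_specificity(
    peaks: PeakMatrix,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Tissue sharing and intensity of ATAC peaks present in the focal tissue.

    A peak is present in a tissue when its sample-presence fraction
    strictly exceeds the threshold; only peaks present in the focal
    tissue are profiled.  The sharing count is the number of tissues in
    which the peak is present (focal included), binned as 1-2 / 3-8 /
    9-15 / 16-18 / 19.  Intensity is the focal presence fraction, binned
    into five groups whose sizes match the sharing-bin sizes (highest
    intensity paired with the most specific sharing bin).
    """
    present = peaks.values > presence_threshold
    focal = present[:, peaks.focal_index]
    ids = np.asarray(peaks.peak_ids)[focal]
    sharing = present[focal].sum(axis=1)
    intensity = peaks.values[focal, peaks.focal_index]
    sharing_bin = _sharing_bin(sharing)

    order = np.argsort(-intensity, kind="stable")
    sizes = [int((sharing_bin == lab).sum()) for lab, *_ in SHARING_BIN_EDGES]
    intensity_bin = np.empty(len(ids), dtype=object)
    start = 0
    for (lab, *_), size in zip(SHARING_BIN_EDGES, sizes):
        intensity_bin[order[start : start + size]] = lab
        start += size
    return pd.DataFrame(
        {
            "id": ids,
            "focal_tissue": peaks.focal_tissue,
            "sharing_count": sharing,
            "sharing_bin": sharing_bin,
            "intensity": intensity,
            "intensity_bin": intensity_bin,
        }
    )
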