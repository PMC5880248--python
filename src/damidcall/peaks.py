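"""Merging fragment-level tests into peak regions.

Tested fragments are clustered along the genome: consecutive retained
fragments are linked when the gap between them is at most ``tol`` bp
(default 260, the median GATC fragment size on mm10), and any linked
run wider than ``max_width`` bp (default 10,000) is split into
near-equal sub-clusters.  Each cluster gets a Simes combined p-value
``min_k (m * p_(k) / k)`` over its m members — valid under positive
dependence and sensitive to a single strong member — followed by
Benjamini–Hochberg adjustment across clusters.  A region is called a
peak when its FDR is below 0.1 and the logFC of its most significant
member exceeds 0.5 (Dam-POI enrichment only; depleted regions are
reported but never called).

The high-confidence filter keeps peaks with a high mean abundance
(mean log2 peak CPM > 4.5 across Dam-POI replicates) and low
between-replicate variability (coefficient of variation < 0.75).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PeakCallParams",
    "merge_windows",
    "simes_p",
    "combine_tests",
    "call_peaks",
    "select_high_confidence",
    "write_peaks",
    "read_peaks",
]


@dataclass
class PeakCallParams:
    tol: int = 260
    max_width: int = 10_000
    fdr: float = 0.1
    min_logfc: float = 0.5
    # high-confidence thresholds
    min_log2_count: float = 4.5
    max_cv: float = 0.75

    def __post_init__(self) -> None:
        if self.tol < 0:
            raise ValueError("tol must be non-negative")
        if self.max_width <= 0:
            raise ValueError("max_width must be positive")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr threshold must be in (0, 1]")


def merge_windows(fragments: pd.DataFrame, tol: int = 260,
                  max_width: int = 10_000) -> np.ndarray:
    """Cluster id per fragment row (contiguous ints in genomic order).

    ``fragments`` needs columns chrom, start, end and should be sorted
    by (chrom, start); unsorted input is sorted internally with a
    warning and ids are returned in the original row order.  Fragments
    are linked when ``next.start - prev.end <= tol`` (boundary
    inclusive); a linked run spanning more than ``max_width`` bp is cut
    into ``ceil(span / max_width)`` sub-clusters of near-equal span,
    members assigned by midpoint.
    """
    chrom = fragments["chrom"].to_numpy()
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    n = len(fragments)
    order = np.arange(n)
    sorted_ok = True
    for i in range(1, n):
        if chrom[i] == chrom[i - 1] and start[i] < start[i - 1]:
            sorted_ok = False
            break
    if not sorted_ok:
        logger.warning("fragments not sorted by (chrom, start); sorting internally")
        order = np.lexsort((start, chrom))
        chrom, start, end = chrom[order], start[order], end[order]

    cluster = np.empty(n, dtype=np.int64)
    next_id = 0
    i = 0
    while i < n:
        j = i + 1
        while j < n and chrom[j] == chrom[i] and start[j] - end[j - 1] <= tol:
            j += 1
        span = end[j - 1] - start[i]
        if span <= max_width:
            cluster[i:j] = next_id
            next_id += 1
        else:
            k = int(np.ceil(span / max_width))
            bounds = start[i] + span * np.arange(1, k) / k
            mid = (start[i:j] + end[i:j]) / 2.0
            sub = np.searchsorted(bounds, mid, side="right")
            # renumber so every sub-cluster id is used contiguously
            _, sub = np.unique(sub, return_inverse=True)
            cluster[i:j] = next_id + sub
            next_id += sub.max() + 1
        i = j
    out = np.empty(n, dtype=np.int64)
    out[order] = cluster
    return out


def simes_p(p_values: np.ndarray) -> float:
    """Simes combined p-value: min over k of m * p_(k) / k."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = len(p)
    return float(np.min(m * p / np.arange(1, m + 1)))


def combine_tests(tests: pd.DataFrame, cluster_ids: np.ndarray) -> pd.DataFrame:
    """Region table from per-fragment tests and a cluster assignment.

    ``tests`` needs columns chrom, start, end, fragment, p_value, logFC.
    Per cluster: Simes combined p, BH-adjusted FDR across clusters, and
    the representative logFC of the smallest-p member (ties broken by
    smallest fragment index).
    """
    df = tests.copy()
    df["_cluster"] = np.asarray(cluster_ids)
    rows = []
    for cid, grp in df.groupby("_cluster", sort=True):
        p = grp["p_value"].to_numpy(dtype=float)
        best = grp.sort_values(["p_value", "fragment"]).iloc[0]
        rows.append({
            "region": int(cid),
            "chrom": grp["chrom"].iloc[0],
            "start": int(grp["start"].min()),
            "end": int(grp["end"].max()),
            "n_members": len(grp),
            "p_simes": simes_p(p),
            "logFC": float(best["logFC"]),
            "best_fragment": int(best["fragment"]),
            "members": ",".join(str(int(f)) for f in grp["fragment"]),
        })
    regions = pd.DataFrame(rows)
    if len(regions):
        regions["fdr"] = multipletests(regions["p_simes"], method="fdr_bh")[1]
    else:
        regions["fdr"] = pd.Series(dtype=float)
    return regions


def call_peaks(regions: pd.DataFrame,
               params: PeakCallParams | None = None) -> pd.DataFrame:
    """Peaks: FDR strictly below threshold AND representative logFC above.

    Only Dam-POI enrichment (positive logFC) is ever called.
    """
    params = params or PeakCallParams()
    if len(regions) == 0:
        out = regions.copy()
        out["called"] = pd.Series(dtype=bool)
        return out
    out = regions.copy()
    out["called"] = (out["fdr"] < params.fdr) & (out["logFC"] > params.min_logfc)
    return out


def peak_replicate_cpm(regions: pd.DataFrame, counts: np.ndarray,
                       fragment_index: np.ndarray,
                       library_sizes: np.ndarray) -> np.ndarray:
    """Per-region, per-sample CPM: sum of member-fragment CPM."""
    cpm = counts / np.asarray(library_sizes, dtype=float)[None, :] * 1e6
    pos = {int(f): i for i, f in enumerate(np.asarray(fragment_index))}
    out = np.zeros((len(regions), counts.shape[1]))
    for r, members in enumerate(regions["members"]):
        idx = [pos[int(f)] for f in str(members).split(",")]
        out[r] = cpm[idx].sum(axis=0)
    return out


def select_high_confidence(peaks: pd.DataFrame, replicate_cpm: np.ndarray,
                           min_log2_count: float = 4.5,
                           max_cv: float = 0.75) -> pd.DataFrame:
    """High-confidence subset: strong and reproducible peaks.

    ``replicate_cpm`` holds the Dam-POI replicate CPM per peak (rows
    aligned with ``peaks``).  Keeps peaks whose mean log2 CPM exceeds
    ``min_log2_count`` and whose coefficient of variation (sd / mean
    across replicates) is below ``max_cv``.  Needs >= 2 replicates.
    """
    replicate_cpm = np.asarray(replicate_cpm, dtype=float)
    if replicate_cpm.ndim != 2 or replicate_cpm.shape[1] < 2:
        raise ValueError("need >= 2 replicates for a coefficient of variation")
    if replicate_cpm.shape[0] != len(peaks):
        raise ValueError("replicate_cpm rows must align with peaks")
    with np.errstate(divide="ignore"):
        mean_log2 = np.log2(replicate_cpm).mean(axis=1)
    mean = replicate_cpm.mean(axis=1)
    sd = replicate_cpm.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    out = peaks.copy()
    out["mean_log2_cpm"] = mean_log2
    out["cv"] = cv
    keep = (mean_log2 > min_log2_count) & (cv < max_cv)
    return out[keep].reset_index(drop=True)


def write_peaks(regions: pd.DataFrame, prefix) -> tuple[str, str]:
    """Write a region table as <prefix>.tsv and called peaks as <prefix>.bed.

    BED score is -log10(fdr) capped at 1000 (fdr = 0 maps to the cap).
    """
    tsv = f"{prefix}.tsv"
    bed = f"{prefix}.bed"
    regions.to_csv(tsv, sep="\t", index=False)
    called = regions[regions["called"]] if "called" in regions else regions
    with open(bed, "w") as fh:
        for i, row in enumerate(called.itertuples(index=False)):
            fdr = row.fdr
            score = 1000.0 if fdr <= 0 else min(1000.0, -np.log10(fdr))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tpeak_{i + 1}"
                     f"\t{score:.4g}\n")
    return tsv, bed


def read_peaks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
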