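"""Read-coverage tracks: per-base depth, CPM scaling, Dam subtraction.

Coverage is stored as run-length intervals (start, end, value) per
chromosome.  Sample tracks are scaled to counts-per-million on TMM
effective library sizes so that Dam-only and Dam-POI tracks are
comparable, and the visual binding signal is the piecewise difference
Dam-POI minus Dam-only (negative values retained — depletion is
informative too).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "genome_coverage",
    "scale_coverage",
    "subtract_tracks",
    "mean_tracks",
    "write_bedgraph",
    "read_bedgraph",
    "write_bigwig",
]


def _canonical(starts: np.ndarray, ends: np.ndarray,
               values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge adjacent runs with equal value; drop empty runs."""
    keep = ends > starts
    starts, ends, values = starts[keep], ends[keep], values[keep]
    if len(starts) == 0:
        return starts, ends, values
    out_s, out_e, out_v = [starts[0]], [ends[0]], [values[0]]
    for s, e, v in zip(starts[1:], ends[1:], values[1:]):
        if s == out_e[-1] and v == out_v[-1]:
            out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
            out_v.append(v)
    return (np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64),
            np.array(out_v, dtype=float))


@dataclass
class CoverageTrack:
    """Run-length coverage per chromosome: chrom -> (starts, ends, values)."""

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict)
    label: str = ""
    scale_factor: float = 1.0

    def area(self) -> float:
        """Sum of value x length over all runs."""
        return float(sum(((e - s) * v).sum() for s, e, v in self.runs.values()))

    def canonicalize(self) -> "CoverageTrack":
        self.runs = {c: _canonical(*r) for c, r in self.runs.items()}
        return self


def genome_coverage(reads_by_chrom: dict[str, list[tuple[int, int]]],
                    chrom_sizes: dict[str, int],
                    label: str = "") -> CoverageTrack:
    """Per-base read depth collapsed to runs of equal value.

    ``reads_by_chrom`` maps chromosome to (start, end) alignment spans.
    Reads extending past the chromosome end are clipped with a warning.
    Only nonzero-depth runs are emitted.
    """
    track = CoverageTrack(label=label)
    for chrom, reads in reads_by_chrom.items():
        if chrom not in chrom_sizes:
            logger.warning("skipping reads on unknown chromosome %s", chrom)
            continue
        size = chrom_sizes[chrom]
        if not reads:
            continue
        arr = np.array(reads, dtype=np.int64)
        if np.any(arr[:, 1] > size) or np.any(arr[:, 0] < 0):
            logger.warning("clipping reads beyond bounds on %s", chrom)
            arr = np.clip(arr, 0, size)
        arr = arr[arr[:, 1] > arr[:, 0]]
        bps = np.concatenate((arr[:, 0], arr[:, 1]))
        deltas = np.concatenate((np.ones(len(arr)), -np.ones(len(arr))))
        order = np.argsort(bps, kind="stable")
        bps, deltas = bps[order], deltas[order]
        uniq, idx = np.unique(bps, return_index=True)
        depth = np.add.reduceat(deltas, idx).cumsum()
        starts, ends, values = _canonical(uniq[:-1], uniq[1:], depth[:-1])
        nz = values != 0
        track.runs[chrom] = (starts[nz], ends[nz], values[nz])
    return track


def scale_coverage(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Multiply every run value by ``factor`` (e.g. 1e6 / effective library)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    out = CoverageTrack(label=track.label,
                        scale_factor=track.scale_factor * factor)
    out.runs = {c: (s.copy(), e.copy(), v * factor)
                for c, (s, e, v) in track.runs.items()}
    return out.canonicalize()


def _step_values(breaks: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                 values: np.ndarray) -> np.ndarray:
    """Evaluate a run-length step function at interval left edges (0 in gaps)."""
    if len(starts) == 0:
        return np.zeros(len(breaks))
    idx = np.searchsorted(starts, breaks, side="right") - 1
    ok = (idx >= 0)
    idx_safe = np.clip(idx, 0, len(starts) - 1)
    inside = ok & (breaks < ends[idx_safe])
    return np.where(inside, values[idx_safe], 0.0)


def subtract_tracks(poi: CoverageTrack, dam: CoverageTrack) -> CoverageTrack:
    """Piecewise POI minus Dam over the union of breakpoints.

    Uncovered positions count as depth 0; negative differences are
    retained.  Chromosomes present in only one input are restricted to
    the intersection with a warning.
    """
    chroms = [c for c in poi.runs if c in dam.runs]
    missing = (set(poi.runs) ^ set(dam.runs))
    if missing:
        logger.warning("chromosomes %s present in only one track; "
                       "restricting to the intersection", sorted(missing))
    out = CoverageTrack(label=f"{poi.label}-minus-{dam.label}")
    for chrom in chroms:
        ps, pe, pv = poi.runs.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))
        ds, de, dv = dam.runs.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))
        breaks = np.unique(np.concatenate((ps, pe, ds, de)))
        if len(breaks) < 2:
            continue
        left = breaks[:-1]
        diff = (_step_values(left, ps, pe, pv) - _step_values(left, ds, de, dv))
        out.runs[chrom] = _canonical(left, breaks[1:], diff)
    return out


def mean_tracks(tracks: list[CoverageTrack], label: str = "") -> CoverageTrack:
    """Mean of several (scaled) tracks — the merged group track."""
    if not tracks:
        raise ValueError("need at least one track")
    out = CoverageTrack(label=label)
    chroms: list[str] = []
    for t in tracks:
        for c in t.runs:
            if c not in chroms:
                chroms.append(c)
    for chrom in chroms:
        parts = [t.runs.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))
                 for t in tracks]
        breaks = np.unique(np.concatenate(
            [np.concatenate((s, e)) for s, e, _ in parts]))
        if len(breaks) < 2:
            continue
        left = breaks[:-1]
        acc = np.zeros(len(left))
        for s, e, v in parts:
            acc += _step_values(left, s, e, v)
        out.runs[chrom] = _canonical(left, breaks[1:], acc / len(tracks))
    return out


def write_bedgraph(track: CoverageTrack, path, omit_zero: bool = True) -> None:
    """4-column bedGraph, sorted, canonical (no adjacent equal runs)."""
    track = track.canonicalize()
    with open(path, "w") as fh:
        for chrom in track.runs:
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                if omit_zero and v == 0:
                    continue
                text = f"{v:.6g}"
                fh.write(f"{chrom}\t{s}\t{e}\t{text}\n")


def read_bedgraph(path, label: str = "") -> CoverageTrack:
    track = CoverageTrack(label=label or str(path))
    data: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()
            data.setdefault(chrom, []).append((int(s), int(e), float(v)))
    for chrom, rows in data.items():
        rows.sort()
        arr_s = np.array([r[0] for r in rows], dtype=np.int64)
        arr_e = np.array([r[1] for r in rows], dtype=np.int64)
        arr_v = np.array([r[2] for r in rows], dtype=float)
        track.runs[chrom] = _canonical(arr_s, arr_e, arr_v)
    return track


def write_bigwig(track: CoverageTrack, path,
                 chrom_sizes: dict[str, int]) -> bool:
    """bigWig output when pyBigWig is importable; returns False otherwise.

    Callers fall back to bedGraph with a notice when unavailable.
    """
    try:
        import pyBigWig
    except ImportError:
        logger.info("pyBigWig not available; keep the bedGraph output instead")
        return False
    track = track.canonicalize()
    bw = pyBigWig.open(str(path), "w")
    header = [(c, chrom_sizes[c]) for c in track.runs if c in chrom_sizes]
    bw.addHeader(header)
    for chrom, _ in header:
        starts, ends, values = track.runs[chrom]
        if len(starts):
            bw.addEntries([chrom] * len(starts), starts.tolist(),
                          ends=ends.tolist(), values=values.tolist())
    bw.close()
    return True
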