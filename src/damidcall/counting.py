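"""Alignment filtering and reads-per-fragment counting.

Reads are kept only if they are primary, mapped, on an informative
contig, and outside any exclusion region (e.g. the ENCODE blacklist).
PCR duplicates are deliberately retained: DamID reads start from
restriction-fragment ends, so identical positions are expected and
duplicate marking would over-remove genuine signal.

A read is assigned to a fragment only when its alignment lies *fully
within* the fragment (start >= fragment start and end <= fragment end);
reads spanning a GATC cut are ambiguous products of partial digestion
and count toward no fragment.  Library size is the number of reads
passing the filters, whether or not they were assignable — this is the
sequencing-depth notion the normalization uses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .fragment_map import FragmentMap

__all__ = [
    "ReadFilterPolicy",
    "FilterStats",
    "SampleSheet",
    "CountMatrix",
    "filter_alignments",
    "count_fragments",
    "count_sample",
    "count_samples",
    "write_counts",
    "read_counts",
    "read_sample_sheet",
]

# contig name patterns the paper's analysis treats as uninformative
DEFAULT_EXCLUDED_CONTIG_PATTERNS = (r"_alt$", r"_random$", r"^chrUn", r"^chrM$", r"^MT$")

GROUP_DAM = "Dam"
GROUP_POI = "DamPOI"

@dataclass
class ReadFilterPolicy:
    """Which alignments survive into counting.

    Duplicate handling is fixed to "keep": DamID-seq retains PCR
    duplicates by design.
    """

    drop_unmapped: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    excluded_contig_patterns: Sequence[str] = DEFAULT_EXCLUDED_CONTIG_PATTERNS
    exclusion_regions: dict[str, np.ndarray] = field(default_factory=dict)
    # exclusion_regions: chrom -> (n, 2) sorted, merged [start, end) intervals

    def contig_excluded(self, name: str) -> bool:
        return any(re.search(p, name) for p in self.excluded_contig_patterns)

    @staticmethod
    def load_exclusion_bed(path) -> dict[str, np.ndarray]:
        """Read a BED of regions to exclude, merged per chromosome."""
        regions: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split()[:3]
                regions.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in regions.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.array(out, dtype=np.int64)
        return merged

@dataclass
class FilterStats:
    total: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    excluded_contig: int = 0
    excluded_region: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

@dataclass
class SampleSheet:
    """Sample identifiers, group labels (Dam / DamPOI), replicates, paths."""

    samples: list[str]
    groups: list[str]
    replicates: list[int]
    paths: list[str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        bad = set(self.groups) - {GROUP_DAM, GROUP_POI}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; "
                             f"expected {GROUP_DAM!r} or {GROUP_POI!r}")

    def __len__(self) -> int:
        return len(self.samples)

def read_sample_sheet(path) -> SampleSheet:
    """TSV with columns: sample, group, replicate, path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "replicate", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return SampleSheet(
        samples=df["sample"].astype(str).tolist(),
        groups=df["group"].astype(str).tolist(),
        replicates=df["replicate"].astype(int).tolist(),
        paths=df["path"].astype(str).tolist(),
    )

@dataclass
class CountMatrix:
    """Integer reads-per-fragment by sample, with library sizes and groups.

    Row order follows the FragmentMap; ``fragment_index`` ties rows back
    to genomic coordinates after filtering.
    """

    counts: np.ndarray              # (fragments, samples) non-negative ints
    fragment_index: np.ndarray      # (fragments,) indices into the map
    samples: list[str]
    groups: list[str]
    library_sizes: np.ndarray       # (samples,) reads passing filters

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.fragment_index = np.asarray(self.fragment_index, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.fragment_index), len(self.samples)):
            raise ValueError("count matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_fragments(self) -> int:
        return self.counts.shape[0]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups])

    def subset_fragments(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[mask], self.fragment_index[mask],
                           list(self.samples), list(self.groups),
                           self.library_sizes.copy())

def filter_alignments(alignments: Iterable, policy: ReadFilterPolicy,
                      stats: FilterStats | None = None,
                      ) -> Iterator[pysam.AlignedSegment]:
    """Yield alignments passing the filter policy, tallying removals.

    Each removed read is attributed to the first rule that rejects it,
    in the order unmapped > secondary > supplementary > contig > region.
    """
    if stats is None:
        stats = FilterStats()
    for aln in alignments:
        stats.total += 1
        if policy.drop_unmapped and aln.is_unmapped:
            stats.unmapped += 1
            continue
        if policy.drop_secondary and aln.is_secondary:
            stats.secondary += 1
            continue
        if policy.drop_supplementary and aln.is_supplementary:
            stats.supplementary += 1
            continue
        chrom = aln.reference_name
        if chrom is None or policy.contig_excluded(chrom):
            stats.excluded_contig += 1
            continue
        regions = policy.exclusion_regions.get(chrom)
        if regions is not None and len(regions):
            start, end = aln.reference_start, aln.reference_end
            # overlap iff some region has r.start < end and r.end > start
            i = np.searchsorted(regions[:, 0], end, side="left")
            if i > 0 and regions[i - 1, 1] > start:
                stats.excluded_region += 1
                continue
        stats.retained += 1
        yield aln

def _assign_fragments(starts: np.ndarray, ends: np.ndarray,
                      bounds: np.ndarray) -> np.ndarray:
    """Fragment ordinal for each read on one chromosome, -1 if spanning.

    ``bounds`` are the cut positions including 0 and the chromosome end;
    fragment i is [bounds[i], bounds[i+1]).  A read is contained iff no
    cut falls strictly inside (start, end) — equivalently the fragment
    containing its start also contains its end.
    """
    idx = np.searchsorted(bounds, starts, side="right") - 1
    valid = (idx >= 0) & (idx < len(bounds) - 1)
    idx_safe = np.clip(idx, 0, len(bounds) - 2)
    contained = valid & (ends <= bounds[idx_safe + 1])
    return np.where(contained, idx_safe, -1)

def count_fragments(reads_by_sample: dict[str, Iterable], fmap: FragmentMap,
                    sheet: SampleSheet,
                    library_sizes: dict[str, int] | None = None) -> CountMatrix:
    """Count already-filtered reads fully contained in fragments.

    ``reads_by_sample`` maps sample id to an iterable of aligned
    segments (pysam) or plain ``(chrom, start, end)`` tuples.  Library
    sizes default to the number of reads seen per sample.
    """
    offsets: dict[str, tuple[int, np.ndarray]] = {}
    base = 0
    for chrom, arr in fmap.chrom_fragments.items():
        bounds = np.concatenate((arr[:, 0], [arr[-1, 1]]))
        offsets[chrom] = (base, bounds)
        base += len(arr)
    counts = np.zeros((fmap.n_fragments, len(sheet)), dtype=np.int64)
    libs = np.zeros(len(sheet), dtype=np.int64)

    for s_i, sample in enumerate(sheet.samples):
        n_reads = 0
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for read in reads_by_sample.get(sample, ()):
            if isinstance(read, tuple):
                chrom, start, end = read
            else:
                chrom, start, end = (read.reference_name, read.reference_start,
                                     read.reference_end)
            n_reads += 1
            if chrom in offsets:
                per_chrom.setdefault(chrom, []).append((start, end))
        for chrom, pairs in per_chrom.items():
            off, bounds = offsets[chrom]
            arr = np.array(pairs, dtype=np.int64)
            assigned = _assign_fragments(arr[:, 0], arr[:, 1], bounds)
            assigned = assigned[assigned >= 0]
            np.add.at(counts[:, s_i], off + assigned, 1)
        libs[s_i] = (library_sizes or {}).get(sample, n_reads)

    return CountMatrix(counts, np.arange(fmap.n_fragments), list(sheet.samples),
                       list(sheet.groups), libs)

def count_sample(path, fmap: FragmentMap, policy: ReadFilterPolicy,
                 ) -> tuple[np.ndarray, int, FilterStats]:
    """Filter and count one SAM/BAM file; returns (counts, library size, stats)."""
    stats = FilterStats()
    sheet = SampleSheet(["_x"], [GROUP_DAM], [1], [str(path)])
    try:
        afile = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read alignments for {path}: {exc}") from exc
    with afile:
        filtered = filter_alignments(afile, policy, stats)
        cm = count_fragments({"_x": filtered}, fmap, sheet)
    return cm.counts[:, 0], stats.retained, stats

def count_samples(sheet: SampleSheet, fmap: FragmentMap,
                  policy: ReadFilterPolicy | None = None,
                  ) -> tuple[CountMatrix, dict[str, FilterStats]]:
    """Full counting stage: filter + count every sample in the sheet."""
    policy = policy or ReadFilterPolicy()
    counts = np.zeros((fmap.n_fragments, len(sheet)), dtype=np.int64)
    libs = np.zeros(len(sheet), dtype=np.int64)
    all_stats: dict[str, FilterStats] = {}
    for i, (sample, path) in enumerate(zip(sheet.samples, sheet.paths)):
        try:
            col, lib, stats = count_sample(path, fmap, policy)
        except IOError as exc:
            raise IOError(f"sample {sample!r}: {exc}") from exc
        counts[:, i] = col
        libs[i] = lib
        all_stats[sample] = stats
    cm = CountMatrix(counts, np.arange(fmap.n_fragments), list(sheet.samples),
                     list(sheet.groups), libs)
    return cm, all_stats

def write_counts(matrix: CountMatrix, path) -> None:
    """Counts as TSV with a ``#``-prefixed header block (groups, libraries)."""
    with open(path, "w") as fh:
        fh.write("# damidcall counts\n")
        fh.write("# samples: " + "\t".join(matrix.samples) + "\n")
        fh.write("# groups: " + "\t".join(matrix.groups) + "\n")
        fh.write("# library_sizes: "
                 + "\t".join(str(int(x)) for x in matrix.library_sizes) + "\n")
        df = pd.DataFrame(matrix.counts, columns=matrix.samples)
        df.insert(0, "fragment", matrix.fragment_index)
        df.to_csv(fh, sep="\t", index=False)

def read_counts(path) -> CountMatrix:
    """Inverse of :func:`write_counts`; lossless round trip."""
    samples = groups = libs = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# samples:"):
                samples = line.split(":", 1)[1].strip().split("\t")
            elif line.startswith("# groups:"):
                groups = line.split(":", 1)[1].strip().split("\t")
            elif line.startswith("# library_sizes:"):
                libs = [int(x) for x in line.split(":", 1)[1].split()]
    if samples is None or groups is None or libs is None:
        raise ValueError(f"{path}: malformed counts header "
                         "(need samples, groups, library_sizes lines)")
    df = pd.read_csv(path, sep="\t", comment="#")
    return CountMatrix(df[samples].to_numpy(dtype=np.int64),
                       df["fragment"].to_numpy(dtype=np.int64),
                       samples, groups, np.array(libs, dtype=np.int64))
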