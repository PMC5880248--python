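"""GATC (DpnI) restriction-fragment partition of a genome.

DamID methylates adenines within GATC motifs; after DpnI digestion the
genome falls into fragments bounded by consecutive GATC sites.  Every
downstream step — counting, testing, peak merging — operates on this
fixed partition, so the fragment map is the coordinate system of the
pipeline.

The DpnI cut is blunt, between GA and TC, i.e. at offset +2 inside every
``GATC`` occurrence.  Any consistent within-motif offset would shift all
boundaries identically; +2 matches the enzyme.  GATC cannot overlap
itself, so occurrences never collide.  ``N`` (or any non-ACGT base)
breaks a match; matching is case-insensitive.  Coordinates are 0-based
half-open throughout, which is also native BED.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GatcFragment",
    "FragmentMap",
    "build_fragment_map",
    "median_fragment_size",
    "write_fragment_annotation",
    "read_fragment_annotation",
]

_MOTIF = re.compile(b"GATC")
_VALID = re.compile(rb"[ACGTURYSWKMBDHVN]*\Z")  # IUPAC nucleotide codes


@dataclass(frozen=True)
class GatcFragment:
    """One DpnI fragment: half-open interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    index: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragmentMap:
    """Ordered, non-overlapping GATC fragments tiling each chromosome.

    ``chrom_fragments`` maps chromosome name to an ``(n, 2)`` int array of
    ``[start, end)`` rows, sorted and adjacent; ``chrom_lengths`` records
    the span each tiling must cover.  Fragment indices are assigned
    genome-wide in chromosome order.
    """

    genome_label: str
    chrom_fragments: dict[str, np.ndarray] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_fragments(self) -> int:
        return sum(len(a) for a in self.chrom_fragments.values())

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_fragments)

    def __iter__(self) -> Iterator[GatcFragment]:
        idx = 0
        for chrom, arr in self.chrom_fragments.items():
            for start, end in arr:
                yield GatcFragment(chrom, int(start), int(end), idx)
                idx += 1

    def fragment_lengths(self) -> np.ndarray:
        """Genome-wide vector of fragment lengths, in map order."""
        if not self.chrom_fragments:
            return np.empty(0, dtype=np.int64)
        parts = [arr[:, 1] - arr[:, 0] for arr in self.chrom_fragments.values()]
        return np.concatenate(parts)

    def to_frame(self) -> pd.DataFrame:
        """Flat table with columns chrom, start, end, index."""
        rows = {"chrom": [], "start": [], "end": []}
        for chrom, arr in self.chrom_fragments.items():
            rows["chrom"].extend([chrom] * len(arr))
            rows["start"].extend(arr[:, 0].tolist())
            rows["end"].extend(arr[:, 1].tolist())
        df = pd.DataFrame(rows)
        df["index"] = np.arange(len(df), dtype=np.int64)
        return df

    def validate(self) -> None:
        """Assert the per-chromosome tiling invariants."""
        for chrom, arr in self.chrom_fragments.items():
            length = self.chrom_lengths[chrom]
            if len(arr) == 0:
                raise ValueError(f"chromosome {chrom!r} has no fragments")
            if arr[0, 0] != 0 or arr[-1, 1] != length:
                raise ValueError(f"fragments on {chrom!r} do not span [0, {length})")
            if np.any(arr[1:, 0] != arr[:-1, 1]):
                raise ValueError(f"fragments on {chrom!r} are not adjacent")
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"empty fragment on {chrom!r}")


def _iter_fasta(source) -> Iterator[tuple[str, bytes]]:
    """Yield (name, uppercase sequence) records from FASTA path/handle."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        opener = gzip.open if path.suffix == ".gz" else open
        handle = opener(path, "rb")
        close = True
    else:
        handle = source
        close = False
    try:
        name = None
        chunks: list[bytes] = []
        for raw in handle:
            line = raw if isinstance(raw, bytes) else raw.encode()
            line = line.strip()
            if not line:
                continue
            if line.startswith(b">"):
                if name is not None:
                    yield name, b"".join(chunks).upper()
                name = line[1:].split()[0].decode()
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence before first header")
                chunks.append(line)
        if name is not None:
            yield name, b"".join(chunks).upper()
    finally:
        if close:
            handle.close()


def gatc_cut_positions(sequence: bytes | str) -> np.ndarray:
    """DpnI cut positions (motif start + 2) in an uppercase sequence."""
    if isinstance(sequence, str):
        sequence = sequence.upper().encode()
    return np.array([m.start() + 2 for m in _MOTIF.finditer(sequence)], dtype=np.int64)


def build_fragment_map(genome, label: str | None = None,
                       contigs: Sequence[str] | None = None) -> FragmentMap:
    """Partition a genome into DpnI GATC fragments.

    Parameters
    ----------
    genome
        FASTA path (plain or gzip), open handle, or a mapping of
        chromosome name to sequence string.
    label
        Free-text genome label stored on the map.
    contigs
        Optional whitelist of chromosome names to keep (e.g. standard
        chromosomes only); ``None`` keeps everything.

    A chromosome with no GATC yields a single fragment spanning it.
    Raises ``ValueError`` for an empty FASTA or non-IUPAC characters.
    """
    if isinstance(genome, Mapping):
        records: Iterator[tuple[str, bytes]] = (
            (name, str(seq).upper().encode()) for name, seq in genome.items()
        )
        default_label = "dict"
    else:
        records = _iter_fasta(genome)
        default_label = str(genome) if isinstance(genome, (str, Path)) else "stream"

    fmap = FragmentMap(genome_label=label or default_label)
    for name, seq in records:
        if contigs is not None and name not in contigs:
            continue
        if len(seq) == 0:
            raise ValueError(f"chromosome {name!r} has empty sequence")
        if not _VALID.match(seq):
            bad = set(seq) - set(b"ACGTURYSWKMBDHVN")
            raise ValueError(
                f"chromosome {name!r} contains non-IUPAC characters: "
                f"{sorted(chr(b) for b in bad)}"
            )
        if name in fmap.chrom_fragments:
            raise ValueError(f"duplicate chromosome name {name!r}")
        cuts = gatc_cut_positions(seq)
        bounds = np.concatenate(([0], cuts, [len(seq)]))
        arr = np.column_stack((bounds[:-1], bounds[1:]))
        fmap.chrom_fragments[name] = arr
        fmap.chrom_lengths[name] = len(seq)
    if not fmap.chrom_fragments:
        raise ValueError("no chromosomes found in genome input")
    return fmap


def median_fragment_size(fmap: FragmentMap) -> float:
    """Median fragment length in bp (mean of central pair for even counts)."""
    lengths = fmap.fragment_lengths()
    if lengths.size == 0:
        raise ValueError("fragment map is empty")
    return float(np.median(lengths))


def write_fragment_annotation(fmap: FragmentMap, path, format: str = "bed") -> None:
    """Write the map as BED (chrom, start, end, index) or tabular TSV.

    Both carry the genome-wide fragment index as a stable identifier; the
    tabular form adds a header line and the genome label.
    """
    df = fmap.to_frame()
    path = Path(path)
    if format == "bed":
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.index}\n")
    elif format in ("tsv", "tabular"):
        with open(path, "w") as fh:
            fh.write(f"# genome: {fmap.genome_label}\n")
            for chrom, length in fmap.chrom_lengths.items():
                fh.write(f"# contig: {chrom}\t{length}\n")
            df.to_csv(fh, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_fragment_annotation(path, chrom_lengths: Mapping[str, int] | None = None,
                             label: str = "") -> FragmentMap:
    """Rebuild a FragmentMap from a BED or tabular annotation file.

    BED files carry no chromosome lengths, so either pass
    ``chrom_lengths`` or rely on the last fragment's end per chromosome
    (exact for maps written by :func:`write_fragment_annotation`).
    """
    path = Path(path)
    lengths: dict[str, int] = dict(chrom_lengths or {})
    header_lengths: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline()
        is_tabular = first.startswith("#") or first.startswith("chrom")
    if is_tabular:
        lab = label
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# genome:"):
                    lab = line.split(":", 1)[1].strip()
                elif line.startswith("# contig:"):
                    name, ln = line.split(":", 1)[1].strip().split("\t")
                    header_lengths[name] = int(ln)
        df = pd.read_csv(path, sep="\t", comment="#")
        label = lab
    else:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "index"])
    fmap = FragmentMap(genome_label=label or str(path))
    for chrom, grp in df.groupby("chrom", sort=False):
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        fmap.chrom_fragments[str(chrom)] = arr
        fmap.chrom_lengths[str(chrom)] = int(
            lengths.get(chrom, header_lengths.get(chrom, arr[-1, 1]))
        )
    fmap.validate()
    return fmap
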