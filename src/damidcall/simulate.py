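"""Seeded synthetic DamID-seq data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a genome with GATC motifs at geometric spacing (default per-position
  rate 1/256, the expected motif density of uniform random sequence);
* a fragment-level *accessibility* propensity shared by both groups —
  untethered Dam methylates open chromatin promiscuously, so Dam-only
  background tracks accessibility rather than being flat;
* a subset of fragments carrying true POI binding, boosting Dam-POI
  (but not Dam-only) means by a configured log2 effect;
* negative-binomial replicate noise around those means;
* reads of fixed length emitted uniformly *fully inside* fragments, as
  DamID-seq fragments are sequenced between GATC cut sites.

Everything flows from a single seed through one named generator, so a
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import CountMatrix, GROUP_DAM, GROUP_POI
from .fragment_map import FragmentMap, build_fragment_map

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_fragment_map",
    "simulate_counts",
    "simulate_reads",
    "write_sam",
    "evaluate_calls",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror a typical DamID-seq design: three replicates per
    group, 50 bp single-end reads, a 4-fold (log2 = 2) POI enrichment
    on 1% of fragments, moderate negative-binomial overdispersion
    (phi = 0.1) and log-normal accessibility spread (sigma = 0.75).
    """

    n_chromosomes: int = 1
    chromosome_length: int = 1_000_000
    gatc_rate: float = 1.0 / 256.0
    n_dam: int = 3
    n_poi: int = 3
    mean_depth: float = 50.0          # expected reads per fragment
    accessibility_mu: float = 0.0     # log-normal location of propensity
    accessibility_sigma: float = 0.75
    binding_fraction: float = 0.01
    effect: float = 2.0               # log2 enrichment in Dam-POI samples
    dispersion: float = 0.1           # NB: var = mu + phi mu^2
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.binding_fraction <= 1):
            raise ValueError("binding fraction must be in [0, 1]")
        for name in ("chromosome_length", "gatc_rate", "mean_depth",
                     "read_length", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def groups(self) -> list[str]:
        return [GROUP_DAM] * self.n_dam + [GROUP_POI] * self.n_poi

    def samples(self) -> list[str]:
        return ([f"Dam_{i + 1}" for i in range(self.n_dam)]
                + [f"DamPOI_{i + 1}" for i in range(self.n_poi)])


@dataclass
class GroundTruth:
    """Indices of truly bound fragments and their log2 effects."""

    binding_fragments: np.ndarray
    beta: np.ndarray  # per-fragment log2 effect over the whole map

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fragment": self.binding_fragments,
                             "beta": self.beta[self.binding_fragments]})


def _chromosome_sequence(length: int, rate: float,
                         rng: np.random.Generator) -> bytes:
    """Random sequence with GATC planted at geometric spacing.

    Background bases are i.i.d. uniform; accidental GATC matches in the
    background are destroyed (the C mutated to A) so the realized motif
    rate is the configured one.
    """
    seq = rng.choice(_BASES, size=length).astype(np.uint8)
    # plant motif starts: gap ~ Geometric(rate) between motif end and next start
    starts = []
    pos = int(rng.geometric(rate) - 1)
    while pos + 4 <= length:
        starts.append(pos)
        pos += 4 + int(rng.geometric(rate) - 1)
    motif = np.frombuffer(b"GATC", dtype=np.uint8)
    for s in starts:
        seq[s:s + 4] = motif
    # destroy accidental motifs that are not planted
    planted = np.zeros(length, dtype=bool)
    for s in starts:
        planted[s] = True
    window = np.lib.stride_tricks.sliding_window_view(seq, 4)
    hits = np.nonzero((window == motif).all(axis=1))[0]
    for h in hits:
        if not planted[h]:
            seq[h + 3] = ord("A")  # GATC -> GATA
    return seq.tobytes()


def simulate_genome(config: SimulationConfig,
                    fasta_path=None) -> tuple[dict[str, str], FragmentMap,
                                              GroundTruth]:
    """Generate a genome, its fragment map, and planted binding truth.

    Returns the sequences (chrom -> string), the map, and the truth;
    optionally writes a FASTA.  Deterministic under the config seed.
    """
    rng = config.rng()
    genome: dict[str, str] = {}
    for c in range(config.n_chromosomes):
        seq = _chromosome_sequence(config.chromosome_length, config.gatc_rate, rng)
        genome[f"chr{c + 1}"] = seq.decode()
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for name, seq in genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
    fmap = build_fragment_map(genome, label=f"simulated(seed={config.seed})")
    truth = _plant_truth(config, fmap.n_fragments, rng)
    return genome, fmap, truth


def _plant_truth(config: SimulationConfig, n_fragments: int,
                 rng: np.random.Generator) -> GroundTruth:
    n_bind = int(round(config.binding_fraction * n_fragments))
    chosen = np.sort(rng.choice(n_fragments, size=n_bind, replace=False))
    beta = np.zeros(n_fragments)
    beta[chosen] = config.effect
    return GroundTruth(chosen, beta)


def simulate_fragment_map(config: SimulationConfig,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[FragmentMap, GroundTruth]:
    """Fragment map with geometric lengths, without sequence synthesis.

    Statistically equivalent coordinates for count-level simulations
    where the nucleotide sequence itself is not needed.
    """
    rng = rng if rng is not None else config.rng()
    fmap = FragmentMap(genome_label=f"simulated-coords(seed={config.seed})")
    base = 0
    for c in range(config.n_chromosomes):
        cuts = []
        pos = 2 + int(rng.geometric(config.gatc_rate) - 1)
        while pos < config.chromosome_length - 2:
            cuts.append(pos)
            pos += 4 + int(rng.geometric(config.gatc_rate) - 1)
        bounds = np.concatenate(([0], cuts, [config.chromosome_length]))
        name = f"chr{c + 1}"
        fmap.chrom_fragments[name] = np.column_stack((bounds[:-1], bounds[1:]))
        fmap.chrom_lengths[name] = config.chromosome_length
    truth = _plant_truth(config, fmap.n_fragments, rng)
    return fmap, truth


def simulate_counts(config: SimulationConfig, fmap: FragmentMap,
                    truth: GroundTruth,
                    rng: np.random.Generator | None = None) -> CountMatrix:
    """Negative-binomial fragment counts with accessibility background.

    Fragment f in sample s has mean
    ``depth * n_frag * w_fs / sum_f w_fs`` with
    ``w_fs = a_f * 2^(beta_f [s in Dam-POI])``, so each sample's
    expected total matches the configured depth; counts are NB with
    ``var = mu + phi mu^2`` (Poisson in the phi -> 0 limit).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = fmap.n_fragments
    access = rng.lognormal(config.accessibility_mu, config.accessibility_sigma,
                           size=n)
    groups = config.groups()
    counts = np.zeros((n, len(groups)), dtype=np.int64)
    for s, g in enumerate(groups):
        w = access * np.where(g == GROUP_POI, 2.0 ** truth.beta, 1.0)
        mu = config.mean_depth * n * w / w.sum()
        if config.dispersion > 1e-12:
            size = 1.0 / config.dispersion
            p = size / (size + mu)
            counts[:, s] = rng.negative_binomial(size, p)
        else:
            counts[:, s] = rng.poisson(mu)
    lib = counts.sum(axis=0)
    return CountMatrix(counts, np.arange(n), config.samples(), groups, lib)


def simulate_reads(config: SimulationConfig, fmap: FragmentMap,
                   counts: CountMatrix,
                   rng: np.random.Generator | None = None,
                   ) -> dict[str, list[tuple[str, int, int]]]:
    """Realize each fragment count as reads placed fully inside it.

    Reads are ``read_length`` bp with uniform start positions subject
    to full containment; fragments shorter than a read emit reads
    spanning the whole fragment.  Returns sample -> list of
    (chrom, start, end).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    frags = fmap.to_frame()
    chrom = frags["chrom"].to_numpy()
    fstart = frags["start"].to_numpy()
    fend = frags["end"].to_numpy()
    out: dict[str, list[tuple[str, int, int]]] = {}
    for s, sample in enumerate(counts.samples):
        reads: list[tuple[str, int, int]] = []
        col = counts.counts[:, s]
        for pos_in_matrix, k in enumerate(col):
            if k == 0:
                continue
            f = counts.fragment_index[pos_in_matrix]
            lo, hi = int(fstart[f]), int(fend[f])
            length = min(config.read_length, hi - lo)
            starts = rng.integers(lo, hi - length + 1, size=int(k))
            reads.extend((str(chrom[f]), int(st), int(st) + length)
                         for st in starts)
        out[sample] = reads
    return out


def write_sam(reads_by_sample: dict[str, list[tuple[str, int, int]]],
              fmap: FragmentMap, out_dir, sheet_path=None) -> dict[str, Path]:
    """Write one SAM file per sample (primary, mapped, no duplicate flags)."""
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(fmap.chrom_lengths[c])}
               for c in fmap.chromosomes],
    }
    tid = {c: i for i, c in enumerate(fmap.chromosomes)}
    paths: dict[str, Path] = {}
    for sample, reads in reads_by_sample.items():
        path = out_dir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
            for i, (chrom, start, end) in enumerate(reads):
                a = pysam.AlignedSegment(sam.header)
                a.query_name = f"{sample}:{i}"
                a.reference_id = tid[chrom]
                a.reference_start = start
                a.cigarstring = f"{end - start}M"
                a.mapping_quality = 60
                a.flag = 0
                a.query_sequence = "A" * (end - start)
                sam.write(a)
        paths[sample] = path
    return paths


def evaluate_calls(called_regions: pd.DataFrame, truth: GroundTruth,
                   fmap: FragmentMap) -> tuple[float, float]:
    """(recall, false-discovery proportion) of called regions vs truth.

    A region is a true positive iff it overlaps at least one binding
    fragment; recall is the share of binding fragments covered by any
    called region.  An empty call set scores recall 0, FDP 0.
    """
    frags = fmap.to_frame()
    bind = frags.loc[frags["index"].isin(truth.binding_fragments)]
    if len(called_regions) == 0:
        return 0.0, 0.0
    covered = np.zeros(len(bind), dtype=bool)
    tp_region = np.zeros(len(called_regions), dtype=bool)
    bstart = bind["start"].to_numpy()
    bend = bind["end"].to_numpy()
    bchrom = bind["chrom"].to_numpy()
    for r, row in enumerate(called_regions.itertuples(index=False)):
        hit = ((bchrom == row.chrom) & (bstart < row.end) & (bend > row.start))
        tp_region[r] = hit.any()
        covered |= hit
    recall = float(covered.mean()) if len(bind) else 0.0
    fdp = float(1.0 - tp_region.mean())
    return recall, fdp
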