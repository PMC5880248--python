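"""Partition a small genome into GATC (DpnI) fragments.

The fragment map is the coordinate system of DamID-seq analysis: Dam
methylates GA*TC sites, DpnI cuts them, and reads are counted per
inter-cut fragment.
"""

from damidcall.fragment_map import build_fragment_map, median_fragment_size

genome = {
    "chrA": "AAGATCAATTGATCGGGATCTT",   # three GATC motifs
    "chrB": "ACGTACGTACGT",             # none: one fragment spans it
}

fmap = build_fragment_map(genome, label="toy")
print("fragments (chrom, start, end, index):")
for frag in fmap:
    print(f"  {frag.chrom}\t{frag.start}\t{frag.end}\t{frag.index}")
print(f"median fragment size: {median_fragment_size(fmap):g} bp")

# Each cut sits at +2 inside a GATC (between GA and TC); fragment
# boundaries are consecutive cuts, with chromosome ends closing the
# terminal fragments, so the fragments tile every chromosome exactly.
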