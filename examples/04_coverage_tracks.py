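"""Build scaled coverage tracks and a Dam-subtracted signal track.

Coverage is per-base read depth collapsed to runs; samples are scaled
to CPM so Dam-only and Dam-POI are comparable, and the browser-ready
binding signal is the piecewise difference POI minus Dam.
"""

from damidcall.tracks import genome_coverage, scale_coverage, subtract_tracks

sizes = {"chr1": 1000}
poi_reads = {"chr1": [(0, 50), (25, 75), (30, 80), (400, 450)]}
dam_reads = {"chr1": [(10, 60), (420, 470)]}

poi = scale_coverage(genome_coverage(poi_reads, sizes, "POI"), 1e6 / 4)
dam = scale_coverage(genome_coverage(dam_reads, sizes, "Dam"), 1e6 / 2)
diff = subtract_tracks(poi, dam)

print("POI-minus-Dam signal (chrom start end value):")
starts, ends, values = diff.runs["chr1"]
for s, e, v in zip(starts, ends, values):
    print(f"  chr1\t{s}\t{e}\t{v:+.0f}")

# Positive runs mark POI-enriched intervals; negative runs mark where
# the untethered Dam control alone is higher (open chromatin without
# POI binding).  Values are CPM-scaled depths.
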