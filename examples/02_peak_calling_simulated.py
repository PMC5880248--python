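"""Call peaks on a simulated DamID-seq experiment with known truth.

Simulates ~4k GATC fragments with a shared accessibility background,
plants a 4-fold (log2 = 2) Dam-POI enrichment on 1% of fragments, runs
the statistical pipeline (abundance filter, TMM logCPM, smooth quantile
normalization, moderated t, Simes-merged regions, BH FDR) and scores
the calls against the planted truth.
"""

from damidcall.pipeline import run_from_counts
from damidcall.simulate import (SimulationConfig, evaluate_calls,
                                simulate_counts, simulate_fragment_map)

cfg = SimulationConfig(chromosome_length=1_000_000, seed=11)
rng = cfg.rng()
fmap, truth = simulate_fragment_map(cfg, rng)
counts = simulate_counts(cfg, fmap, truth, rng)

result = run_from_counts(counts, fmap)
recall, fdp = evaluate_calls(result.peaks, truth, fmap)

print(f"fragments simulated:     {fmap.n_fragments}")
print(f"fragments after filter:  {result.report['n_retained']}")
print(f"merged regions tested:   {result.report['n_regions']}")
print(f"peaks called:            {result.report['n_peaks']}"
      f"  (FDR < 0.1, logFC > 0.5)")
print(f"truly bound fragments:   {len(truth.binding_fragments)}")
print(f"recall:                  {recall:.3f}")
print(f"false-discovery prop.:   {fdp:.3f}")

# recall = share of planted binding fragments covered by a called
# region; FDP = share of called regions overlapping no planted
# fragment.  At these study conditions most planted sites are found
# with very few false regions.
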