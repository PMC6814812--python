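"""Quantify repertoire sharing between two strains with the MII.

Simulates the full study design — two strains drawing from repertoires with
75% shared clone identities, 3 mice per strain, 2 biological x 2 technical
replicates — then pools replicates per mouse, applies the >5-count filter,
and computes the all-pairs Mutual Information Index.  MII is 1 for
identical abundance patterns and 0 for disjoint repertoires.
"""

from tcrshare import (
    SimConfig, filter_min_count, merge_replicates, mii_matrix,
    simulate_cohort, strain_summary,
)

cfg = SimConfig(seed=7)
cohort, truth = simulate_cohort(cfg)
print(f"true (generating-distribution) MII between strains: {truth.true_mii:.3f}")

merged, strains = [], {}
for strain, samples in cohort.items():
    by_mouse = {}
    for s in samples:
        by_mouse.setdefault(s.subset, []).append(s)
    for reps in by_mouse.values():
        pooled = filter_min_count(merge_replicates(reps), tau=5)
        merged.append(pooled)
        strains[pooled.sample_id] = strain

matrix = mii_matrix(merged)
print("\nwithin- vs cross-strain MII (mean +/- SD over sample pairs):")
print(strain_summary(matrix, strains).to_string(index=False))
# Within-strain pairs (same generating distribution, independent mice) sit
# near 1; cross-strain pairs recover the true between-strain overlap.
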