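"""Dominant clonotypes across samples and TCR-set coverage.

Builds the dominance matrix — frequencies of one repertoire's 50 most
abundant clonotypes looked up in every sample — and then asks what
fraction of a healthy repertoire's reads is carried by the clonotype set
shared with the disease-model repertoire (set coverage).
"""

from tcrshare import (
    SimConfig, TcrSet, dominance_matrix, sample_reads, set_coverage,
    shared_clonotypes, simulate_pair,
)

cfg = SimConfig(seed=5)
p, q, truth = simulate_pair(cfg)
sf = sample_reads(p, 50_000, seed=6, sample_id="Sf_m1", strain="Sf")
healthy = sample_reads(q, 50_000, seed=7, sample_id="healthy_m1", strain="healthy")

dom = dominance_matrix(sf, [sf, healthy], n=50)
present = (dom["healthy_m1"] > 0).sum()
print(f"dominance matrix: {dom.shape[0]} reference clonotypes x {dom.shape[1]} samples")
print(f"of the 50 dominant Sf clonotypes, {present} are present in the healthy sample")
print(dom.head(5).to_string(float_format=lambda x: f"{x:.4f}"))

shared = shared_clonotypes(sf, healthy, level="nt")
cov = set_coverage(healthy, TcrSet(shared.members, level="nt"))
print(f"\nshared clonotypes: {len(shared)}")
print(f"fraction of healthy reads on shared clonotypes: {cov:.2%}")
# High coverage means the clones dominating the disease-model repertoire
# are not strain-private: the healthy repertoire carries them too.
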