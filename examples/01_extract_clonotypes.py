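"""Extract TCRα CDR3 clonotypes from anchored amplicon reads.

Simulates a skewed 300-clone repertoire, writes 5000 error-free amplicon
reads (V-anchor + CDR3 + C-anchor) as FASTQ, extracts the CDR3 between the
anchors and tabulates clonotype counts.  With no sequencing error the
recovered table matches the generating sample read-for-read.
"""

import tempfile
from pathlib import Path

from tcrshare import (
    SimConfig, build_clonotype_table, extract_cdr3, read_sequences,
    reads_to_fastq, sample_reads, simulate_pair, top_n,
)

cfg = SimConfig(n_clones=300, seed=1)
p, _, _ = simulate_pair(cfg)
sample = sample_reads(p, 5000, seed=2, sample_id="demo")

fastq = Path(tempfile.mkdtemp()) / "reads.fastq"
reads_to_fastq(sample, fastq, error_rate=0.0, seed=0)

table = build_clonotype_table(
    (extract_cdr3(r) for r in read_sequences(fastq)),
    sample_id="demo", v_call="Va2", j_call="Ja2",
)

print(f"reads in: {sample.total_reads}, clonotypes recovered: {len(table)}")
print(f"tables identical: {table.counts == sample.counts}")
print("top 5 clonotypes (nt, aa, count):")
for clone in top_n(table, 5):
    print(f"  {clone.cdr3_nt:<24} {clone.cdr3_aa:<8} {table.counts[clone]}")
# Each row is one clonotype: its CDR3 nucleotide sequence, the translated
# junction, and how many reads carried it.
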