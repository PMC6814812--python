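"""Core repertoire data model.

A repertoire is a table of clonotypes (TCRα CDR3 identities) with read
counts.  This module provides the containers and the elementary operations
the downstream overlap and diversity statistics are built from: replicate
merging, low-abundance filtering, frequency computation, dominant-clone
matrices, amino-acid-level collapsing, shared-clonotype sets and TCR-set
coverage.

Clonotype identity is configurable: the nucleotide-level key
``(cdr3_nt, v_call, j_call)`` is the default for within-strain bookkeeping,
while cross-strain sharing is usually assessed at the amino-acid level
(synonymous nucleotide variants of the same CDR3 protein sequence count as
one TCR; see :func:`collapse_to_aa`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel amino-acid value for CDR3s that do not translate cleanly
#: (out-of-frame length, ambiguous base, or a stop codon).
NONPRODUCTIVE = "NONPRODUCTIVE"

IdentityKey = Literal["nt", "aa"]


@dataclass(frozen=True)
class Clonotype:
    """Identity of one TCRα CDR3: nucleotide and protein sequence plus segment calls."""

    cdr3_nt: str
    cdr3_aa: str = NONPRODUCTIVE
    v_call: str = ""
    j_call: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3_nt:
            raise ValueError("cdr3_nt must be non-empty")

    def key(self, level: IdentityKey = "nt") -> tuple[str, str, str]:
        """Clonotype identity tuple at the requested level."""
        if level == "nt":
            return (self.cdr3_nt, self.v_call, self.j_call)
        if level == "aa":
            return (self.cdr3_aa, self.v_call, self.j_call)
        raise ValueError(f"unknown identity level: {level!r}")

    @property
    def productive(self) -> bool:
        return self.cdr3_aa != NONPRODUCTIVE


@dataclass
class RepertoireSample:
    """One population's clonotype -> count table with sample metadata."""

    sample_id: str
    counts: dict[Clonotype, int] = field(default_factory=dict)
    strain: str = ""
    organ: str = ""
    subset: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        for clone, n in self.counts.items():
            if not isinstance(n, int) or isinstance(n, bool) or n <= 0:
                raise ValueError(
                    f"count for {clone.cdr3_nt} must be a positive integer, got {n!r}"
                )

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RepertoireSample):
            return NotImplemented
        return (
            self.counts == other.counts
            and self.strain == other.strain
            and self.organ == other.organ
            and self.subset == other.subset
        )


def frequencies(sample: RepertoireSample) -> dict[Clonotype, float]:
    """Per-clonotype relative frequencies count/total; sums to 1.

    Raises ``ValueError`` on an empty sample.
    """
    total = sample.total_reads
    if total == 0:
        raise ValueError(f"sample {sample.sample_id!r} is empty; frequencies undefined")
    return {clone: n / total for clone, n in sample.counts.items()}


def merge_replicates(
    samples: list[RepertoireSample], method: Literal["sum_counts"] = "sum_counts"
) -> RepertoireSample:
    """Pool replicate sequencing runs of one population by summing counts.

    All inputs must agree on strain/organ/subset; the merged sample_id records
    the provenance of the constituent runs.
    """
    if method != "sum_counts":
        raise ValueError(f"unknown merge method: {method!r}")
    if not samples:
        raise ValueError("no samples to merge")
    head = samples[0]
    for s in samples[1:]:
        if (s.strain, s.organ, s.subset) != (head.strain, head.organ, head.subset):
            raise ValueError(
                "cannot merge replicates with mismatched metadata: "
                f"{(head.strain, head.organ, head.subset)} vs "
                f"{(s.strain, s.organ, s.subset)}"
            )
    merged: dict[Clonotype, int] = {}
    for s in samples:
        for clone, n in s.counts.items():
            merged[clone] = merged.get(clone, 0) + n
    sample_id = "+".join(s.sample_id for s in samples)
    return RepertoireSample(
        sample_id=sample_id,
        counts=merged,
        strain=head.strain,
        organ=head.organ,
        subset=head.subset,
        replicate="merged",
    )


def filter_min_count(sample: RepertoireSample, tau: int = 5) -> RepertoireSample:
    """Drop clonotypes seen ``tau`` times or fewer (keep counts strictly > tau).

    The default tau=5 keeps only CDR3s observed more than five times in the
    population, the abundance filter applied before all repertoire statistics.
    An empty result is permitted.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    kept = {clone: n for clone, n in sample.counts.items() if n > tau}
    return replace(sample, counts=kept)


def top_n(
    sample: RepertoireSample, n: int = 50, level: IdentityKey = "nt"
) -> list[Clonotype]:
    """The ``n`` most abundant clonotypes, descending; ties broken by cdr3_nt.

    Returns the whole repertoire when it holds fewer than ``n`` clonotypes.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ranked = sorted(sample.counts.items(), key=lambda kv: (-kv[1], kv[0].cdr3_nt))
    return [clone for clone, _ in ranked[:n]]


def dominance_matrix(
    reference: RepertoireSample,
    samples: list[RepertoireSample],
    n: int = 50,
    level: IdentityKey = "nt",
) -> pd.DataFrame:
    """Frequencies of the reference's top-``n`` clonotypes across samples.

    Rows follow the reference's dominance order; a clonotype absent from a
    sample contributes 0.  Row labels are ``junction_aa|junction`` so the
    matrix is readable as the classic dominant-TCR heatmap input.
    """
    ref_top = top_n(reference, n=n, level=level)
    columns = {}
    for s in samples:
        freq_by_key: dict[tuple, float] = {}
        for clone, f in frequencies(s).items():
            k = clone.key(level)
            freq_by_key[k] = freq_by_key.get(k, 0.0) + f
        columns[s.sample_id] = [freq_by_key.get(c.key(level), 0.0) for c in ref_top]
    index = [f"{c.cdr3_aa}|{c.cdr3_nt}" for c in ref_top]
    return pd.DataFrame(columns, index=index)


def collapse_to_aa(
    sample: RepertoireSample,
) -> tuple[RepertoireSample, dict[tuple[str, str, str], set[str]]]:
    """Re-key a repertoire at the amino-acid level.

    Counts of synonymous nucleotide variants are summed within identical
    ``(cdr3_aa, v_call, j_call)``.  Returns the collapsed sample plus a map
    from each aa-level key to the set of nucleotide sequences encoding it,
    supporting "N TCRs encoded by M nucleotide sequences" reporting.
    Nonproductive clonotypes are excluded (their read count is logged).
    """
    collapsed: dict[Clonotype, int] = {}
    variants: dict[tuple[str, str, str], set[str]] = {}
    by_key: dict[tuple[str, str, str], Clonotype] = {}
    dropped_reads = 0
    for clone, n in sample.counts.items():
        if not clone.productive:
            dropped_reads += n
            continue
        k = clone.key("aa")
        rep = by_key.get(k)
        if rep is None:
            # representative keeps the first nt sequence seen (lexicographic
            # stability enforced below via sorted iteration is unnecessary:
            # counts and variant sets are order-independent)
            rep = Clonotype(
                cdr3_nt=clone.cdr3_nt,
                cdr3_aa=clone.cdr3_aa,
                v_call=clone.v_call,
                j_call=clone.j_call,
            )
            by_key[k] = rep
            variants[k] = set()
        collapsed[rep] = collapsed.get(rep, 0) + n
        variants[k].add(clone.cdr3_nt)
    if dropped_reads:
        logger.info(
            "collapse_to_aa: excluded %d nonproductive reads from %s",
            dropped_reads,
            sample.sample_id,
        )
    out = replace(sample, counts=collapsed)
    return out, variants


@dataclass
class TcrSet:
    """A labelled set of clonotype identity keys (e.g. autoreactive TCRs)."""

    members: set[tuple[str, str, str]]
    label: str = ""
    level: IdentityKey = "nt"

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_clonotypes(
        cls, clones: Iterable[Clonotype], label: str = "", level: IdentityKey = "nt"
    ) -> "TcrSet":
        return cls(members={c.key(level) for c in clones}, label=label, level=level)


def shared_clonotypes(
    a: RepertoireSample, b: RepertoireSample, level: IdentityKey = "aa"
) -> TcrSet:
    """Clonotype keys present in both repertoires (aa-level by default)."""
    keys_a = {c.key(level) for c in a.counts}
    keys_b = {c.key(level) for c in b.counts}
    return TcrSet(
        members=keys_a & keys_b,
        label=f"shared:{a.sample_id}&{b.sample_id}",
        level=level,
    )


def set_coverage(sample: RepertoireSample, tcrs: TcrSet) -> float:
    """Fraction of a repertoire's reads carried by clonotypes in ``tcrs``.

    This is the statistic behind "autoreactive TCRs accounted for X% of CDR3
    regions sequenced": the summed frequency of the sample's clonotypes whose
    identity key belongs to the query set.
    """
    if len(tcrs) == 0:
        raise ValueError("coverage of an empty TCR set is undefined")
    freq = frequencies(sample)
    return sum(f for clone, f in freq.items() if clone.key(tcrs.level) in tcrs.members)
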