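"""Sequencing-read and clonotype-table I/O plus anchored CDR3 extraction.

The amplicon design fixes constant sequence on both sides of the TCRα CDR3:
the 3' end of the Vα segment upstream and the Cα-proximal constant region
downstream.  Extraction therefore reduces to locating the two anchors
(allowing a small Hamming mismatch budget for sequencing error) and taking
the subsequence strictly between them.  No germline alignment or CDR3 motif
calling is attempted: in the fixed Vα2/Jα context the anchors fully define
the junction boundaries.

All read-internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .repcore import NONPRODUCTIVE, Clonotype, RepertoireSample

# Gene-specific 3' portions of the library-amplification primers flanking the
# CDR3: Va2 upstream, Ca downstream.  These are the default extraction anchors.
DEFAULT_V_ANCHOR = "CTGGAGACTCAGCT"
DEFAULT_J_ANCHOR = "TTAACTGGTACACAGCAG"

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequencingRead:
    """One raw read: id, DNA sequence, optional per-base quality scores."""

    read_id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class AnchorConfig:
    """Anchor sequences delimiting the CDR3 and the mismatch tolerance."""

    v_anchor: str = DEFAULT_V_ANCHOR
    j_anchor: str = DEFAULT_J_ANCHOR
    max_mismatches: int = 1
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        for name, anchor in (("v_anchor", self.v_anchor), ("j_anchor", self.j_anchor)):
            if len(anchor) < 10:
                raise ValueError(f"{name} must be at least 10 nt, got {len(anchor)}")
            bad = set(anchor) - _DNA
            if bad:
                raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be non-negative")
        limit = min(len(self.v_anchor), len(self.j_anchor)) / 2
        if self.max_mismatches >= limit:
            raise ValueError(
                f"max_mismatches={self.max_mismatches} too permissive for anchor "
                f"lengths {len(self.v_anchor)}/{len(self.j_anchor)}"
            )


@dataclass
class ExtractionResult:
    """An extracted CDR3: nucleotide sequence, translation, and source strand."""

    cdr3_nt: str
    cdr3_aa: str
    strand: Literal["+", "-"]


#: Returned by extract_cdr3 when the anchors cannot be located.
NO_MATCH = None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_sequences(
    path: str | Path, format: Literal["fasta", "fastq", "auto"] = "auto"
) -> Iterator[SequencingRead]:
    """Stream reads from a FASTA/FASTQ file, plain or gzipped.

    ``format="auto"`` infers the format from the filename (``.fastq``/``.fq``
    suffixes, before an optional ``.gz``, mean FASTQ; anything else FASTA).
    Records are yielded in file order with ids preserved; an empty file yields
    an empty stream.  Malformed records raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    if format == "auto":
        suffix = Path(stem).suffix.lower()
        format = "fastq" if suffix in {".fastq", ".fq"} else "fasta"

    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as handle:
        try:
            for record in SeqIO.parse(handle, format):
                quality = None
                if format == "fastq":
                    quality = list(record.letter_annotations["phred_quality"])
                yield SequencingRead(
                    read_id=record.id, sequence=str(record.seq).upper(), quality=quality
                )
        except ValueError as exc:
            raise ValueError(f"malformed {format} record in {path}: {exc}") from exc


def _best_match(seq: str, anchor: str, start: int, max_mismatches: int) -> int | None:
    """Leftmost position (>= start) of the lowest-mismatch Hamming occurrence.

    Returns None if no window is within the mismatch budget.  A 0-mismatch
    window short-circuits: no later window can beat it and earlier windows
    were already worse.
    """
    best_pos: int | None = None
    best_mm = max_mismatches + 1
    la = len(anchor)
    for pos in range(start, len(seq) - la + 1):
        mm = 0
        window = seq[pos : pos + la]
        for a, b in zip(window, anchor):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_mm = mm
            best_pos = pos
            if mm == 0:
                break
    return best_pos if best_mm <= max_mismatches else None


def extract_cdr3(
    read: SequencingRead, anchors: AnchorConfig | None = None
) -> ExtractionResult | None:
    """Locate the CDR3 between the V and J anchors of a read.

    The V anchor is searched first; the J anchor is then searched strictly
    downstream of it.  Each anchor matches at the leftmost position achieving
    the minimal Hamming distance within ``max_mismatches``.  If the + strand
    fails and ``search_both_strands`` is set, the reverse complement is tried.
    Returns ``NO_MATCH`` (None) when either anchor is absent, the anchors are
    out of order, or the CDR3 between them is empty — degenerate reads are
    data, not errors.
    """
    if anchors is None:
        anchors = AnchorConfig()

    def try_strand(seq: str, strand: Literal["+", "-"]) -> ExtractionResult | None:
        v_pos = _best_match(seq, anchors.v_anchor, 0, anchors.max_mismatches)
        if v_pos is None:
            return NO_MATCH
        cdr3_start = v_pos + len(anchors.v_anchor)
        j_pos = _best_match(seq, anchors.j_anchor, cdr3_start, anchors.max_mismatches)
        if j_pos is None:
            return NO_MATCH
        cdr3_nt = seq[cdr3_start:j_pos]
        if not cdr3_nt:
            return NO_MATCH
        return ExtractionResult(
            cdr3_nt=cdr3_nt, cdr3_aa=translate_cdr3(cdr3_nt), strand=strand
        )

    result = try_strand(read.sequence, "+")
    if result is NO_MATCH and anchors.search_both_strands:
        result = try_strand(reverse_complement(read.sequence), "-")
    return result


def translate_cdr3(cdr3_nt: str) -> str:
    """Standard-code frame-0 translation of a CDR3 nucleotide sequence.

    Returns :data:`~tcrshare.repcore.NONPRODUCTIVE` when the length is not a
    multiple of 3, the sequence contains an ambiguous base (N), or the
    translation contains a stop codon (the junction sits mid-protein, so any
    stop is disruptive).  Non-DNA characters raise ``ValueError``.
    """
    if not cdr3_nt:
        raise ValueError("empty CDR3 sequence")
    seq = cdr3_nt.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in CDR3: {sorted(bad)}")
    if len(seq) % 3 != 0 or "N" in seq:
        return NONPRODUCTIVE
    aa = str(Seq(seq).translate())
    if "*" in aa:
        return NONPRODUCTIVE
    return aa


def build_clonotype_table(
    extractions: Iterable[ExtractionResult | None],
    sample_id: str = "",
    v_call: str = "",
    j_call: str = "",
    **metadata: str,
) -> RepertoireSample:
    """Tabulate extraction results into a clonotype count table.

    ``NO_MATCH`` entries are skipped.  Counting is order-independent: the
    resulting table depends only on the multiset of extracted CDR3s.
    """
    counts: dict[Clonotype, int] = {}
    for res in extractions:
        if res is NO_MATCH:
            continue
        clone = Clonotype(
            cdr3_nt=res.cdr3_nt, cdr3_aa=res.cdr3_aa, v_call=v_call, j_call=j_call
        )
        counts[clone] = counts.get(clone, 0) + 1
    return RepertoireSample(sample_id=sample_id, counts=counts, **metadata)


# --- AIRR Rearrangement-style TSV --------------------------------------------

MANDATORY_COLUMNS = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count"]
METADATA_COLUMNS = ["sample_id", "strain", "organ", "subset", "replicate"]


def read_clonotype_table(path: str | Path) -> RepertoireSample:
    """Read a clonotype count table (AIRR Rearrangement dialect TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    counts: dict[Clonotype, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = getattr(row, "duplicate_count")
        try:
            n = int(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path} line {i}: duplicate_count {raw!r} is not an integer"
            ) from None
        if n <= 0:
            raise ValueError(f"{path} line {i}: duplicate_count must be positive, got {n}")
        clone = Clonotype(
            cdr3_nt=getattr(row, "junction"),
            cdr3_aa=getattr(row, "junction_aa") or NONPRODUCTIVE,
            v_call=getattr(row, "v_call"),
            j_call=getattr(row, "j_call"),
        )
        counts[clone] = counts.get(clone, 0) + n

    meta = {}
    for col in METADATA_COLUMNS:
        if col in df.columns and len(df) > 0:
            meta[col] = df[col].iloc[0]
        else:
            meta[col] = ""
    return RepertoireSample(
        sample_id=meta["sample_id"] or path.stem,
        counts=counts,
        strain=meta["strain"],
        organ=meta["organ"],
        subset=meta["subset"],
        replicate=meta["replicate"],
    )


def write_clonotype_table(sample: RepertoireSample, path: str | Path) -> None:
    """Write a clonotype table as AIRR-style TSV (lossless for counts/sequences).

    Rows are sorted by descending count then cdr3_nt so output is deterministic.
    """
    total = sample.total_reads
    rows = []
    ranked = sorted(sample.counts.items(), key=lambda kv: (-kv[1], kv[0].cdr3_nt))
    for clone, n in ranked:
        rows.append(
            {
                "sample_id": sample.sample_id,
                "strain": sample.strain,
                "organ": sample.organ,
                "subset": sample.subset,
                "replicate": sample.replicate,
                "junction": clone.cdr3_nt,
                "junction_aa": clone.cdr3_aa,
                "v_call": clone.v_call,
                "j_call": clone.j_call,
                "duplicate_count": n,
                "frequency": n / total if total else 0.0,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS + MANDATORY_COLUMNS[:4] +
                 ["duplicate_count", "frequency"]).to_csv(path, sep="\t", index=False)
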