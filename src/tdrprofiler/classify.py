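"""Adapter trimming, size filtering, and sequential class assignment.

Reads are assigned by a strict priority rule: the first class in the fixed
order rRNA -> miRNA -> tRNA -> piRNA with at least one hit wins.  Reads with
no class hit fall through to the genome (both strands); an antisense overlap
of an annotated gene makes the read an endo-siRNA, a sense overlap an mRNA
fragment, anything else other_genomic.  A read with no hit anywhere is
unassigned.  Among equal-class hits the minimal-mismatch targets share
weight equally, so one read always contributes exactly one unit of weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO

from .index import Hit, SequenceIndex
from .reference import CLASS_ORDER, ReferenceSet

ALL_LABELS = (
    "rRNA",
    "miRNA",
    "tRNA",
    "piRNA",
    "endo_siRNA",
    "mRNA_frag",
    "other_genomic",
    "unassigned",
)
GENOME_MAPPING_LABELS = ALL_LABELS[:-1]


@dataclass
class Read:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")


@dataclass(frozen=True)
class AssignedTarget:
    record_id: str
    start: int  # 1-based on the record / contig plus strand
    strand: str
    mismatches: int
    weight: float
    gene_id: Optional[str] = None  # for genomic hits overlapping a gene


@dataclass
class ReadAssignment:
    read_id: str
    class_label: str
    targets: Tuple[AssignedTarget, ...]
    read_length: int
    first_nt: str

    def __post_init__(self) -> None:
        if self.class_label not in ALL_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.class_label == "unassigned" and self.targets:
            raise ValueError("unassigned reads must have no targets")


def read_fastq(path: Path) -> List[Read]:
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def trim_adapter(sequence: str, adapter: str, min_prefix: int = 6) -> str:
    """Cut at the leftmost occurrence of an adapter prefix of >= min_prefix nt.

    The adapter may run off the 3' end of the read (a truncated occurrence
    counts as long as >= min_prefix adapter bases match).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    probe = adapter[:min_prefix]
    n = len(sequence)
    i = sequence.find(probe)
    while i != -1:
        k = min(len(adapter), n - i)
        if sequence[i : i + k] == adapter[:k]:
            return sequence[:i]
        i = sequence.find(probe, i + 1)
    return sequence


def trim_and_filter(
    reads: Iterable[Read],
    adapter: str,
    min_len: int = 18,
    max_len: int = 40,
) -> List[Read]:
    """Adapter-trim then keep inserts in the size-selected [min_len, max_len] window."""
    out = []
    for r in reads:
        seq = trim_adapter(r.sequence, adapter)
        if min_len <= len(seq) <= max_len:
            out.append(Read(r.read_id, seq))
    return out


def _gene_overlaps(
    refset: ReferenceSet, hit: Hit, read_len: int
) -> List[Tuple[str, str]]:
    """Genes overlapping the hit window, as (gene_id, sense|antisense)."""
    lo, hi = hit.start, hit.start + read_len - 1
    out = []
    for g in refset.genes:
        if g.contig == hit.record_id and g.start <= hi and lo <= g.end:
            out.append((g.gene_id, "sense" if g.strand == hit.strand else "antisense"))
    return out


def _min_mm(hits: List[Hit]) -> List[Hit]:
    best = min(h.mismatches for h in hits)
    return [h for h in hits if h.mismatches == best]


def assign_class(read: Read, index: SequenceIndex, refset: ReferenceSet) -> ReadAssignment:
    """Classify a single read by the sequential priority rule."""
    label, targets = _assign(read.sequence, index, refset)
    return ReadAssignment(
        read_id=read.read_id,
        class_label=label,
        targets=targets,
        read_length=len(read.sequence),
        first_nt=read.sequence[0],
    )


def _assign(
    seq: str, index: SequenceIndex, refset: ReferenceSet
) -> Tuple[str, Tuple[AssignedTarget, ...]]:
    for label in CLASS_ORDER:
        hits = index.query_class(label, seq)
        if hits:
            hits = _min_mm(hits)
            w = 1.0 / len(hits)
            return label, tuple(
                AssignedTarget(h.record_id, h.start, h.strand, h.mismatches, w)
                for h in hits
            )
    ghits = index.query_genome(seq)
    if not ghits:
        return "unassigned", ()
    ghits = _min_mm(ghits)
    anti: List[Tuple[Hit, str]] = []
    sense: List[Tuple[Hit, str]] = []
    plain: List[Hit] = []
    for h in ghits:
        overlaps = _gene_overlaps(refset, h, len(seq))
        anti_genes = [g for g, o in overlaps if o == "antisense"]
        sense_genes = [g for g, o in overlaps if o == "sense"]
        # a hit overlapping opposite-strand genes both ways: antisense wins
        if anti_genes:
            anti.append((h, anti_genes[0]))
        elif sense_genes:
            sense.append((h, sense_genes[0]))
        else:
            plain.append(h)
    if anti:
        w = 1.0 / len(anti)
        return "endo_siRNA", tuple(
            AssignedTarget(h.record_id, h.start, h.strand, h.mismatches, w, gene_id=g)
            for h, g in anti
        )
    if sense:
        w = 1.0 / len(sense)
        return "mRNA_frag", tuple(
            AssignedTarget(h.record_id, h.start, h.strand, h.mismatches, w, gene_id=g)
            for h, g in sense
        )
    w = 1.0 / len(plain)
    return "other_genomic", tuple(
        AssignedTarget(h.record_id, h.start, h.strand, h.mismatches, w) for h in plain
    )


def classify_reads(
    reads: Iterable[Read], index: SequenceIndex, refset: ReferenceSet
) -> List[ReadAssignment]:
    """Classify many reads, memoizing by sequence (libraries repeat heavily)."""
    cache: Dict[str, Tuple[str, Tuple[AssignedTarget, ...]]] = {}
    out = []
    for r in reads:
        hit = cache.get(r.sequence)
        if hit is None:
            hit = _assign(r.sequence, index, refset)
            cache[r.sequence] = hit
        label, targets = hit
        out.append(
            ReadAssignment(r.read_id, label, targets, len(r.sequence), r.sequence[0])
        )
    return out


@dataclass
class ClassCounts:
    """Weighted per-class totals with the genome-mapping denominator.

    A read hitting only a class reference (e.g. a 3' tDR ending in the
    non-templated CCA) still counts as genome-mapping: the class references
    are genomic features, so class percentages are taken over all
    class-or-genome mapped reads.
    """

    counts: Dict[str, float]
    total_genome_mapping: float
    total_input: float


def count_classes(assignments: Iterable[ReadAssignment]) -> ClassCounts:
    counts = {label: 0.0 for label in ALL_LABELS}
    total_input = 0.0
    for a in assignments:
        total_input += 1
        counts[a.class_label] += sum(t.weight for t in a.targets) if a.targets else 1.0
    total_genome = sum(counts[label] for label in GENOME_MAPPING_LABELS)
    return ClassCounts(counts=counts, total_genome_mapping=total_genome, total_input=total_input)


@dataclass
class NormalizedCounts:
    values: Dict[str, float]
    denominator_kind: str
    denominator: float


DENOMINATOR_KINDS = ("genome", "genome_minus_rRNA", "class_total")


def normalize(
    counts: ClassCounts,
    denominator_kind: str = "genome",
    class_label: Optional[str] = None,
) -> NormalizedCounts:
    """Reads-per-million under one of the three denominator conventions."""
    if denominator_kind == "genome":
        denom = counts.total_genome_mapping
    elif denominator_kind == "genome_minus_rRNA":
        denom = counts.total_genome_mapping - counts.counts.get("rRNA", 0.0)
    elif denominator_kind == "class_total":
        if class_label is None:
            raise ValueError("class_total normalization needs a class_label")
        denom = counts.counts.get(class_label, 0.0)
    else:
        raise ValueError(f"unknown denominator kind {denominator_kind!r}")
    if denom <= 0:
        raise ValueError(f"normalization denominator ({denominator_kind}) is zero")
    values = {
        label: 1e6 * c / denom
        for label, c in counts.counts.items()
        if label != "unassigned"
    }
    return NormalizedCounts(values=values, denominator_kind=denominator_kind, denominator=denom)


def assignments_to_frame(assignments: Iterable[ReadAssignment]) -> pd.DataFrame:
    """Flat per-target table (one row per read-target pair)."""
    rows = []
    for a in assignments:
        if not a.targets:
            rows.append((a.read_id, a.class_label, "", 0, "", 0, 0.0, a.read_length, a.first_nt))
        for t in a.targets:
            rows.append(
                (a.read_id, a.class_label, t.record_id, t.start, t.strand, t.mismatches, t.weight, a.read_length, a.first_nt)
            )
    return pd.DataFrame(
        rows,
        columns=["read_id", "class", "target", "start", "strand", "mismatches", "weight", "length", "first_nt"],
    )
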