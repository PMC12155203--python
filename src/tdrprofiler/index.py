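"""Substring index over the reference collections.

Desk-scale stand-in for a read aligner: finds every ungapped occurrence of a
query read in the class references (sense strand only — small RNAs are
cloned from the mature RNA) and in the genome (both strands), allowing 0 or
1 mismatches.  Identical mature tRNA sequences are collapsed to one record
before indexing, with the member ids kept so isodecoders stay recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .reference import CLASS_ORDER, ReferenceSet, reverse_complement


@dataclass(frozen=True)
class Hit:
    """One ungapped occurrence of a read.

    ``start`` is 1-based on the record's sense (plus) strand; for a minus
    strand genome hit it is the leftmost plus-strand coordinate of the
    matched window.
    """

    source: str  # class label or "genome"
    record_id: str  # class record id or contig name
    start: int
    strand: str  # "+" or "-"
    mismatches: int


def _scan(read: str, ref: str, max_mm: int) -> List[Tuple[int, int]]:
    """All (1-based start, mismatch count) windows of ref matching read."""
    n, m = len(ref), len(read)
    if m > n:
        return []
    out: List[Tuple[int, int]] = []
    if max_mm == 0:
        i = ref.find(read)
        while i != -1:
            out.append((i + 1, 0))
            i = ref.find(read, i + 1)
        return out
    for i in range(n - m + 1):
        mm = 0
        window = ref[i : i + m]
        if window == read:
            out.append((i + 1, 0))
            continue
        for a, b in zip(window, read):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            out.append((i + 1, mm))
    return out


class SequenceIndex:
    """Query interface over one ReferenceSet at a fixed mismatch tolerance."""

    def __init__(self, refset: ReferenceSet, max_mismatches: int = 0):
        if max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if not refset.genome.contigs and not any(
            refset.classes[c].records for c in CLASS_ORDER
        ):
            raise ValueError("cannot index an empty reference set")
        self.refset = refset
        self.max_mismatches = max_mismatches
        # collapse identical tRNA mature sequences; representative = first id
        self.trna_members: Dict[str, List[str]] = {}
        seen: Dict[str, str] = {}
        collapsed: List[Tuple[str, str]] = []
        for tid, seq in refset.classes["tRNA"].records:
            if seq in seen:
                self.trna_members[seen[seq]].append(tid)
            else:
                seen[seq] = tid
                self.trna_members[tid] = [tid]
                collapsed.append((tid, seq))
        self._class_records: Dict[str, List[Tuple[str, str]]] = {
            label: (collapsed if label == "tRNA" else refset.classes[label].records)
            for label in CLASS_ORDER
        }
        self._genome: List[Tuple[str, str, str]] = [
            (name, seq, reverse_complement(seq))
            for name, seq in refset.genome.contigs.items()
        ]

    def query_class(self, class_label: str, read: str) -> List[Hit]:
        hits: List[Hit] = []
        for rid, seq in self._class_records[class_label]:
            for start, mm in _scan(read, seq, self.max_mismatches):
                hits.append(Hit(class_label, rid, start, "+", mm))
        return hits

    def query_genome(self, read: str) -> List[Hit]:
        hits: List[Hit] = []
        for name, fwd, rev in self._genome:
            n = len(fwd)
            for start, mm in _scan(read, fwd, self.max_mismatches):
                hits.append(Hit("genome", name, start, "+", mm))
            for start, mm in _scan(read, rev, self.max_mismatches):
                # map the reverse-strand window back to plus-strand coords
                plus_start = n - (start - 1) - len(read) + 1
                hits.append(Hit("genome", name, plus_start, "-", mm))
        return hits

    def query(self, read: str) -> List[Hit]:
        """All hits across the four class references and the genome."""
        hits: List[Hit] = []
        for label in CLASS_ORDER:
            hits.extend(self.query_class(label, read))
        hits.extend(self.query_genome(read))
        return hits


def build_class_index(refset: ReferenceSet, max_mismatches: int = 0) -> SequenceIndex:
    return SequenceIndex(refset, max_mismatches)
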