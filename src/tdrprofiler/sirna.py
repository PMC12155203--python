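"""Endogenous siRNA quantification.

endo-siRNAs are reads mapping antisense to annotated mRNAs.  The strict
22G-RNA class additionally requires a read length of exactly 22 nt and a 5'
guanosine (as sequenced, not the templated base); 26G-RNAs are the 26 nt
analogue.  Per-gene totals are reported as reads per million of total
genome-mapping reads.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import pandas as pd

from .classify import ClassCounts, ReadAssignment, count_classes


def per_gene_antisense_counts(
    assignments: Iterable[ReadAssignment],
    counts: Optional[ClassCounts] = None,
) -> pd.DataFrame:
    """Weighted antisense read counts per gene with genome-denominator rpm.

    Genes with no antisense reads are absent from the table.
    """
    assignments = list(assignments)
    if counts is None:
        counts = count_classes(assignments)
    per_gene: Dict[str, float] = {}
    for a in assignments:
        if a.class_label != "endo_siRNA":
            continue
        for t in a.targets:
            if t.gene_id is not None:
                per_gene[t.gene_id] = per_gene.get(t.gene_id, 0.0) + t.weight
    df = pd.DataFrame(
        sorted(per_gene.items()), columns=["gene_id", "count"]
    )
    if counts.total_genome_mapping <= 0:
        raise ValueError("rpm denominator (total genome-mapping reads) is zero")
    df["rpm"] = 1e6 * df["count"] / counts.total_genome_mapping
    return df


def extract_g_class(
    assignments: Iterable[ReadAssignment],
    length: int = 22,
    first_nt: str = "G",
) -> List[ReadAssignment]:
    """Reads satisfying the strict nG-RNA definition: antisense to a gene,
    exactly ``length`` nt, 5' base ``first_nt``."""
    return [
        a
        for a in assignments
        if a.class_label == "endo_siRNA"
        and a.read_length == length
        and a.first_nt == first_nt
    ]


def extract_22g(assignments: Iterable[ReadAssignment]) -> List[ReadAssignment]:
    """22G-RNAs: antisense reads 22 nt long with a 5' G."""
    return extract_g_class(assignments, length=22, first_nt="G")


def extract_26g(assignments: Iterable[ReadAssignment]) -> List[ReadAssignment]:
    """26G-RNAs: antisense reads 26 nt long with a 5' G."""
    return extract_g_class(assignments, length=26, first_nt="G")
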