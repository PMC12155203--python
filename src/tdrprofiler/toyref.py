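"""Deterministic toy reference set bundled with the package.

A miniature stand-in for a worm-like genome annotation at desk scale: a
handful of rRNA/miRNA/piRNA records, ten mature tRNAs covering the
isoacceptor families the tDR analysis cares about (Gly-GCC, Glu-CTC,
Ser-AGA, ...), and six protein-coding genes for the sense/antisense genomic
calls.  Construction is seeded internally so every build is byte-identical
regardless of user seeds.

Sequences are drawn to avoid the 5-mer prefix of the TruSeq small-RNA 3'
adapter (and its reverse complement) so adapter trimming of simulated reads
never cuts inside a real insert.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .reference import (
    ClassAnnotation,
    GeneAnnotation,
    GenomeRef,
    MatureTRNA,
    ReferenceSet,
    reverse_complement,
)

TOY_SEED = 20240601

# (isoacceptor, number of isodecoders)
_TRNA_FAMILIES: List[Tuple[str, int]] = [
    ("Gly-GCC", 2),
    ("Glu-CTC", 2),
    ("Ser-AGA", 1),
    ("His-GTG", 1),
    ("Lys-CTT", 1),
    ("Val-AAC", 1),
    ("Ala-AGC", 1),
    ("Asp-GTC", 1),
]

_FORBIDDEN = ("TGGAA", "TTCCA")  # adapter prefix and its reverse complement


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    bases = np.array(list("ACGT"))
    while True:
        s = "".join(rng.choice(bases, size=length))
        if not any(f in s for f in _FORBIDDEN):
            return s


def _make_trna(rng: np.random.Generator, isoacceptor: str, idx: int) -> MatureTRNA:
    anticodon = isoacceptor.split("-")[1].replace("U", "T")
    while True:
        body = list(_rand_seq(rng, 73))
        body[33:36] = list(anticodon)  # anticodon at mature positions 34-36
        seq = "".join(body) + "CCA"
        if not any(f in seq for f in _FORBIDDEN):
            break
    aa = isoacceptor.split("-")[0]
    return MatureTRNA(
        trna_id=f"trna-{aa}-{anticodon}-{idx}",
        isoacceptor=isoacceptor,
        sequence=seq,
        anticodon_start=34,
        anticodon_end=36,
        isodecoder_index=idx,
    )


def toy_reference_set() -> ReferenceSet:
    """Build the bundled toy ReferenceSet (always identical)."""
    rng = np.random.default_rng(TOY_SEED)

    rrnas = [("rrn-1", _rand_seq(rng, 150)), ("rrn-2", _rand_seq(rng, 120))]
    mirnas = [(f"mir-{i + 1}", _rand_seq(rng, 22)) for i in range(6)]
    pirnas = [(f"21ur-{i + 1}", "T" + _rand_seq(rng, 20)) for i in range(6)]

    trnas: List[MatureTRNA] = []
    for isoacceptor, n in _TRNA_FAMILIES:
        for idx in range(1, n + 1):
            trnas.append(_make_trna(rng, isoacceptor, idx))

    # chrI: spacers + rRNA + tRNA gene bodies (genomic copies lack the CCA)
    parts = [_rand_seq(rng, 100)]
    for _, seq in rrnas:
        parts.append(seq)
        parts.append(_rand_seq(rng, 50))
    for t in trnas:
        parts.append(t.sequence[:-3])
        parts.append(_rand_seq(rng, 40))
    for _, seq in mirnas + pirnas:
        parts.append(seq)
        parts.append(_rand_seq(rng, 30))
    chr1 = "".join(parts)

    # chrII: six 300 nt genes on alternating strands with 80 nt spacers
    genes: List[GeneAnnotation] = []
    pos = 1
    parts = []
    spacer = _rand_seq(rng, 80)
    parts.append(spacer)
    pos += len(spacer)
    for i in range(6):
        strand = "+" if i % 2 == 0 else "-"
        gene_seq = _rand_seq(rng, 300)
        genomic = gene_seq if strand == "+" else reverse_complement(gene_seq)
        genes.append(GeneAnnotation(f"gene-{i + 1}", "chrII", pos, pos + 299, strand))
        parts.append(genomic)
        pos += 300
        spacer = _rand_seq(rng, 80)
        parts.append(spacer)
        pos += len(spacer)
    chr2 = "".join(parts)

    genome = GenomeRef({"chrI": chr1, "chrII": chr2})
    classes = {
        "rRNA": ClassAnnotation("rRNA", rrnas),
        "miRNA": ClassAnnotation("miRNA", mirnas),
        "tRNA": ClassAnnotation("tRNA", [(t.trna_id, t.sequence) for t in trnas]),
        "piRNA": ClassAnnotation("piRNA", pirnas),
    }
    return ReferenceSet(genome=genome, classes=classes, trnas=trnas, genes=genes)


def gene_mrna(refset: ReferenceSet, gene: GeneAnnotation) -> str:
    """The mRNA (sense) sequence of a gene from the genome."""
    seq = refset.genome.contigs[gene.contig][gene.start - 1 : gene.end]
    return seq if gene.strand == "+" else reverse_complement(seq)
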