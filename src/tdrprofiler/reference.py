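"""Reference sequences for small-RNA classification.

The classifier needs four class-annotated sequence collections (rRNA, miRNA,
tRNA, piRNA), a genome, mature tRNA records with anticodon coordinates, and
gene intervals for the genomic sense/antisense calls.  All coordinates are
1-based inclusive; sequences are uppercase DNA (U is converted to T on load).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

CLASS_ORDER: Tuple[str, ...] = ("rRNA", "miRNA", "tRNA", "piRNA")

_VALID_SEQ = re.compile(r"^[ACGT]+$")


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, convert U->T, and reject non-ACGTU characters."""
    s = str(seq).upper().replace("U", "T")
    m = re.search(r"[^ACGT]", s)
    if m:
        raise ValueError(
            f"{context}: invalid character {s[m.start()]!r} at position {m.start() + 1}"
        )
    return s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GenomeRef:
    """Genome as a mapping of contig name -> uppercase ACGT sequence."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            if not _VALID_SEQ.match(seq):
                raise ValueError(f"contig {name!r} contains non-ACGT characters")


@dataclass
class MatureTRNA:
    """One mature tRNA with its anticodon triplet located on the sequence.

    The isoacceptor string (e.g. ``Gly-GCC``) carries the anticodon as
    written 5'->3'; the triplet at ``anticodon_start..anticodon_end`` on the
    mature sense sequence must spell it.  Mature sequences end in the
    non-templated CCA; :func:`load_reference_set` appends it when absent.
    """

    trna_id: str
    isoacceptor: str
    sequence: str
    anticodon_start: int
    anticodon_end: int
    isodecoder_index: int = 1

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, context=f"tRNA {self.trna_id}")
        if self.anticodon_end - self.anticodon_start != 2:
            raise ValueError(
                f"tRNA {self.trna_id}: anticodon must span exactly 3 nt "
                f"({self.anticodon_start}..{self.anticodon_end})"
            )
        if not (1 <= self.anticodon_start < self.anticodon_end <= len(self.sequence)):
            raise ValueError(f"tRNA {self.trna_id}: anticodon coordinates out of range")
        if not self.sequence.endswith("CCA"):
            raise ValueError(f"tRNA {self.trna_id}: mature sequence must end in CCA")
        anticodon = self.isoacceptor.split("-")[-1].upper().replace("U", "T")
        triplet = self.sequence[self.anticodon_start - 1 : self.anticodon_end]
        if triplet != anticodon:
            raise ValueError(
                f"tRNA {self.trna_id}: anticodon coordinates spell {triplet}, "
                f"isoacceptor {self.isoacceptor} expects {anticodon}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ClassAnnotation:
    """One small-RNA class: a label and its (id, sequence) records."""

    class_label: str
    records: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.class_label!r}")
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate record ids in class {self.class_label}")


@dataclass
class GeneAnnotation:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id}: bad interval {self.start}..{self.end}")


@dataclass
class ReferenceSet:
    """Everything the classifier needs, validated."""

    genome: GenomeRef
    classes: Dict[str, ClassAnnotation]
    trnas: List[MatureTRNA]
    genes: List[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.trna_id for t in self.trnas]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate mature tRNA ids")
        for g in self.genes:
            if g.contig not in self.genome.contigs:
                raise ValueError(f"gene {g.gene_id}: unknown contig {g.contig}")
            if g.end > len(self.genome.contigs[g.contig]):
                raise ValueError(f"gene {g.gene_id}: interval beyond contig end")

    def trna_by_id(self, trna_id: str) -> MatureTRNA:
        for t in self.trnas:
            if t.trna_id == trna_id:
                return t
        raise KeyError(trna_id)

    def isoacceptors(self) -> List[str]:
        seen: List[str] = []
        for t in self.trnas:
            if t.isoacceptor not in seen:
                seen.append(t.isoacceptor)
        return seen


def _read_fasta(path: Path) -> List[Tuple[str, str]]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, normalize_sequence(str(rec.seq), context=rec.id)))
    return records


def _load_genes(path: Path) -> List[GeneAnnotation]:
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
        genes = []
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
            genes.append(GeneAnnotation(gid, feat.seqid, feat.start, feat.end, feat.strand))
        return genes
    df = pd.read_csv(path, sep="\t")
    expected = ["gene_id", "contig", "start", "end", "strand"]
    if list(df.columns[:5]) != expected:
        df = pd.read_csv(path, sep="\t", header=None, names=expected)
    return [
        GeneAnnotation(str(r.gene_id), str(r.contig), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def load_trna_table(path: Path) -> List[MatureTRNA]:
    """Read the mature tRNA TSV (trna_id, isoacceptor, sequence,
    anticodon_start, anticodon_end[, isodecoder_index]).

    Appends the non-templated 3' CCA when the mature sequence lacks it; any
    other invariant violation is a hard error naming the tRNA.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"trna_id", "isoacceptor", "sequence", "anticodon_start", "anticodon_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tRNA table missing columns: {sorted(missing)}")
    trnas = []
    for row in df.itertuples():
        if pd.isna(row.anticodon_start) or pd.isna(row.anticodon_end):
            raise ValueError(f"tRNA {row.trna_id}: missing anticodon coordinates")
        seq = normalize_sequence(row.sequence, context=f"tRNA {row.trna_id}")
        if not seq.endswith("CCA"):
            seq = seq + "CCA"
        idx = int(getattr(row, "isodecoder_index", 1) or 1)
        trnas.append(
            MatureTRNA(
                trna_id=str(row.trna_id),
                isoacceptor=str(row.isoacceptor),
                sequence=seq,
                anticodon_start=int(row.anticodon_start),
                anticodon_end=int(row.anticodon_end),
                isodecoder_index=idx,
            )
        )
    return trnas


def load_reference_set(
    genome_fasta: Path,
    class_fastas: Mapping[str, Path],
    trna_table: Path,
    gene_annotation: Path | None = None,
) -> ReferenceSet:
    """Load and validate a full ReferenceSet from disk.

    ``class_fastas`` maps rRNA/miRNA/piRNA labels to FASTA paths; the tRNA
    class is built from the mature tRNA table so that anticodon coordinates
    and sequences always agree.
    """
    contigs = dict(_read_fasta(Path(genome_fasta)))
    if len(contigs) != len(_read_fasta(Path(genome_fasta))):
        raise ValueError("duplicate contig names in genome FASTA")
    genome = GenomeRef(contigs)
    trnas = load_trna_table(Path(trna_table))
    classes: Dict[str, ClassAnnotation] = {}
    for label in ("rRNA", "miRNA", "piRNA"):
        if label in class_fastas:
            classes[label] = ClassAnnotation(label, _read_fasta(Path(class_fastas[label])))
        else:
            classes[label] = ClassAnnotation(label, [])
    classes["tRNA"] = ClassAnnotation("tRNA", [(t.trna_id, t.sequence) for t in trnas])
    genes = _load_genes(Path(gene_annotation)) if gene_annotation else []
    return ReferenceSet(genome=genome, classes=classes, trnas=trnas, genes=genes)


def write_reference_set(refset: ReferenceSet, outdir: Path) -> Dict[str, Path]:
    """Write a ReferenceSet to FASTA/TSV files; inverse of load_reference_set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def _write_fasta(name: str, records: List[Tuple[str, str]]) -> Path:
        p = outdir / f"{name}.fa"
        with open(p, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return p

    paths["genome"] = _write_fasta("genome", list(refset.genome.contigs.items()))
    for label in ("rRNA", "miRNA", "piRNA"):
        paths[label] = _write_fasta(label, refset.classes[label].records)
    trna_df = pd.DataFrame(
        {
            "trna_id": [t.trna_id for t in refset.trnas],
            "isoacceptor": [t.isoacceptor for t in refset.trnas],
            "sequence": [t.sequence for t in refset.trnas],
            "anticodon_start": [t.anticodon_start for t in refset.trnas],
            "anticodon_end": [t.anticodon_end for t in refset.trnas],
            "isodecoder_index": [t.isodecoder_index for t in refset.trnas],
        }
    )
    paths["trna_table"] = outdir / "trnas.tsv"
    trna_df.to_csv(paths["trna_table"], sep="\t", index=False)
    gene_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in refset.genes],
            "contig": [g.contig for g in refset.genes],
            "start": [g.start for g in refset.genes],
            "end": [g.end for g in refset.genes],
            "strand": [g.strand for g in refset.genes],
        }
    )
    paths["genes"] = outdir / "genes.tsv"
    gene_df.to_csv(paths["genes"], sep="\t", index=False)
    return paths
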