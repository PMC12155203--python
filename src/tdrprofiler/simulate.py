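"""Synthetic small-RNA libraries and single-embryo count tables.

The read simulator draws each read's class from a composition profile and
then emits a sequence from the matching generative model:

* tDRs are contiguous substrings of mature tRNAs that either start at
  mature position 1 (5' fragments/halves) or end at the CCA terminus
  (3' fragments); lengths come from a two-mode mixture (a "half" mode around
  31-36 nt and a shorter trimmed-fragment mode).
* rRNA fragments have uniform start positions and a length model skewed
  towards small RNAs, giving a near-uniform first-nucleotide distribution.
* miRNA/piRNA reads are full-length annotated records.
* endo-siRNAs are antisense substrings of annotated genes, 22 or 26 nt,
  with a tunable probability of a 5' G.
* mRNA fragments are sense substrings of genes.
* "unassigned" reads are random sequences verified absent from every
  reference.

Every read carries its ground-truth class (and 5'/3' label for tDRs) so
recovery tests can compare classifier output against truth.  All randomness
flows from a single numpy Generator seeded from the profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .index import SequenceIndex
from .reference import ReferenceSet, reverse_complement
from .toyref import gene_mrna

# TruSeq small RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

CLASS_KEYS = ("rRNA_frag", "tDR", "miRNA", "piRNA", "endo_siRNA", "mRNA_frag", "unassigned")

MIN_LEN, MAX_LEN = 18, 40


@dataclass
class FragmentModel:
    """Length / side / isoacceptor model for tDR generation."""

    five_prime_fraction: float
    half_length_mean: float = 33.5
    half_length_sd: float = 1.5
    short_length_mean: float = 24.0
    short_length_sd: float = 3.0
    long_mode_weight: float = 0.5
    isoacceptor_weights: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.five_prime_fraction, self.long_mode_weight):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.isoacceptor_weights:
            total = sum(self.isoacceptor_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("isoacceptor weights must sum to 1")


@dataclass
class RRNAFragModel:
    """Random-degradation background: uniform start, small-length skew."""

    length_mean: float = 21.0
    length_sd: float = 3.0


@dataclass
class SiRNAModel:
    """endo-siRNA model: 22/26 nt antisense reads with a 5'-G bias."""

    length_weights: Dict[int, float] = field(default_factory=lambda: {22: 0.8, 26: 0.2})
    five_prime_g_prob: float = 0.85

    def __post_init__(self) -> None:
        if set(self.length_weights) - {22, 26}:
            raise ValueError("siRNA lengths must be 22 and/or 26")
        if abs(sum(self.length_weights.values()) - 1.0) > 1e-9:
            raise ValueError("siRNA length weights must sum to 1")


@dataclass
class CompositionProfile:
    """Generative parameters of one synthetic small-RNA library."""

    name: str
    class_fractions: Dict[str, float]
    fragment_model: FragmentModel
    rrna_model: RRNAFragModel = field(default_factory=RRNAFragModel)
    sirna_model: SiRNAModel = field(default_factory=SiRNAModel)
    read_count: int = 100_000
    seed: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.class_fractions) - set(CLASS_KEYS)
        if unknown:
            raise ValueError(f"unknown class keys: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if self.read_count <= 0:
            raise ValueError("read_count must be positive")


@dataclass
class SimRead:
    read_id: str
    sequence: str
    true_class: str
    true_source: str
    true_half: Optional[str] = None  # five_prime / three_prime for tDRs


@dataclass
class SyntheticLibrary:
    reads: List[SimRead]
    profile: CompositionProfile

    def truth_fraction(self, class_key: str) -> float:
        return sum(r.true_class == class_key for r in self.reads) / len(self.reads)


def _draw_length(rng: np.random.Generator, mean: float, sd: float, upper: int) -> int:
    val = int(round(rng.normal(mean, sd)))
    return int(np.clip(val, MIN_LEN, min(MAX_LEN, upper)))


def simulate_small_rna_reads(
    profile: CompositionProfile,
    refset: ReferenceSet,
    seed: Optional[int] = None,
) -> SyntheticLibrary:
    """Draw a library of `profile.read_count` reads with truth labels."""
    rng = np.random.default_rng(profile.seed if seed is None else seed)

    fracs = np.array([profile.class_fractions.get(k, 0.0) for k in CLASS_KEYS])
    active = [k for k, f in zip(CLASS_KEYS, fracs) if f > 0]
    _check_usable(profile, refset, active)

    fm = profile.fragment_model
    iso_names: List[str] = []
    iso_probs: Optional[np.ndarray] = None
    trnas_by_iso: Dict[str, list] = {}
    if "tDR" in active:
        for t in refset.trnas:
            trnas_by_iso.setdefault(t.isoacceptor, []).append(t)
        if fm.isoacceptor_weights:
            iso_names = list(fm.isoacceptor_weights)
            missing = [i for i in iso_names if i not in trnas_by_iso]
            if missing:
                raise ValueError(f"profile weights name unknown isoacceptors: {missing}")
            iso_probs = np.array([fm.isoacceptor_weights[i] for i in iso_names])
        else:
            iso_names = sorted(trnas_by_iso)
            iso_probs = np.full(len(iso_names), 1.0 / len(iso_names))

    sirna_lengths = list(profile.sirna_model.length_weights)
    sirna_probs = np.array([profile.sirna_model.length_weights[L] for L in sirna_lengths])
    mrnas = [(g.gene_id, gene_mrna(refset, g)) for g in refset.genes]
    # start positions giving a 5'-G read (templated C at the fragment 3' end)
    g_starts: Dict[tuple, List[int]] = {}
    for gid, mrna in mrnas:
        for L in sirna_lengths:
            g_starts[(gid, L)] = [
                j for j in range(len(mrna) - L + 1) if mrna[j + L - 1] == "C"
            ]
    unassigned_index = SequenceIndex(refset, 0) if "unassigned" in active else None
    bases = np.array(list("ACGT"))

    labels = rng.choice(len(CLASS_KEYS), size=profile.read_count, p=fracs / fracs.sum())
    reads: List[SimRead] = []
    for i, lab in enumerate(labels):
        key = CLASS_KEYS[lab]
        rid = f"{profile.name}_{i + 1}"
        if key == "tDR":
            iso = iso_names[rng.choice(len(iso_names), p=iso_probs)]
            members = trnas_by_iso[iso]
            t = members[rng.integers(len(members))]
            if rng.random() < fm.long_mode_weight:
                L = _draw_length(rng, fm.half_length_mean, fm.half_length_sd, t.length)
            else:
                L = _draw_length(rng, fm.short_length_mean, fm.short_length_sd, t.length)
            if rng.random() < fm.five_prime_fraction:
                seq, half = t.sequence[:L], "five_prime"
            else:
                seq, half = t.sequence[-L:], "three_prime"
            reads.append(SimRead(rid, seq, "tDR", t.trna_id, half))
        elif key == "rRNA_frag":
            recs = refset.classes["rRNA"].records
            rec_id, rec_seq = recs[rng.integers(len(recs))]
            L = _draw_length(rng, profile.rrna_model.length_mean, profile.rrna_model.length_sd, len(rec_seq))
            start = rng.integers(len(rec_seq) - L + 1)
            reads.append(SimRead(rid, rec_seq[start : start + L], "rRNA_frag", rec_id))
        elif key == "miRNA":
            recs = refset.classes["miRNA"].records
            rec_id, rec_seq = recs[rng.integers(len(recs))]
            reads.append(SimRead(rid, rec_seq, "miRNA", rec_id))
        elif key == "piRNA":
            recs = refset.classes["piRNA"].records
            rec_id, rec_seq = recs[rng.integers(len(recs))]
            reads.append(SimRead(rid, rec_seq, "piRNA", rec_id))
        elif key == "endo_siRNA":
            gid, mrna = mrnas[rng.integers(len(mrnas))]
            L = sirna_lengths[rng.choice(len(sirna_lengths), p=sirna_probs)]
            force_g = rng.random() < profile.sirna_model.five_prime_g_prob
            starts = g_starts[(gid, L)] if force_g else None
            if not starts:
                j = int(rng.integers(len(mrna) - L + 1))
            else:
                j = starts[rng.integers(len(starts))]
            reads.append(SimRead(rid, reverse_complement(mrna[j : j + L]), "endo_siRNA", gid))
        elif key == "mRNA_frag":
            gid, mrna = mrnas[rng.integers(len(mrnas))]
            L = _draw_length(rng, 26.0, 4.0, len(mrna))
            j = rng.integers(len(mrna) - L + 1)
            reads.append(SimRead(rid, mrna[j : j + L], "mRNA_frag", gid))
        else:  # unassigned
            while True:
                L = int(rng.integers(MIN_LEN, MAX_LEN + 1))
                seq = "".join(rng.choice(bases, size=L))
                if not unassigned_index.query(seq):
                    break
            reads.append(SimRead(rid, seq, "unassigned", "random"))
    return SyntheticLibrary(reads=reads, profile=profile)


def _check_usable(profile: CompositionProfile, refset: ReferenceSet, active: Sequence[str]) -> None:
    needs = {
        "rRNA_frag": bool(refset.classes["rRNA"].records),
        "tDR": bool(refset.trnas),
        "miRNA": bool(refset.classes["miRNA"].records),
        "piRNA": bool(refset.classes["piRNA"].records),
        "endo_siRNA": bool(refset.genes),
        "mRNA_frag": bool(refset.genes),
        "unassigned": True,
    }
    for key in active:
        if not needs[key]:
            raise ValueError(f"class {key} has fraction > 0 but no usable reference records")


def write_fastq(
    library: SyntheticLibrary,
    path: Path,
    with_adapter: bool = False,
    adapter: str = DEFAULT_ADAPTER,
    read_length: int = 75,
) -> Path:
    """Write 4-line FASTQ with a constant Phred33 quality.

    With ``with_adapter`` each record is insert + 3' adapter truncated to
    ``read_length`` nt, emulating an untrimmed sequencer read.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for r in library.reads:
            seq = (r.sequence + adapter)[:read_length] if with_adapter else r.sequence
            fh.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def write_truth(library: SyntheticLibrary, path: Path) -> Path:
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in library.reads],
            "true_class": [r.true_class for r in library.reads],
            "true_source": [r.true_source for r in library.reads],
            "true_half": [r.true_half or "" for r in library.reads],
        }
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# single-embryo count tables


@dataclass
class ExpressionProfile:
    """Generative parameters of a synthetic genes x embryos experiment."""

    stage: str
    gene_means: Dict[str, float]
    gene_lengths: Dict[str, int]
    groups: Dict[str, List[str]] = field(default_factory=dict)
    planted_de: List[tuple] = field(default_factory=list)  # (gene, log2fc)
    dispersion: float = 0.02
    n_control: int = 3
    n_treatment: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_control < 2 or self.n_treatment < 2:
            raise ValueError("need at least 2 embryos per condition")
        for gene, _ in self.planted_de:
            if gene not in self.gene_means:
                raise ValueError(f"planted DE gene {gene!r} not in gene_means")


def simulate_embryo_counts(profile: ExpressionProfile, seed: Optional[int] = None):
    """Negative-binomial genes x embryos counts with planted fold changes."""
    from .expression import EmbryoCountTable  # deferred: avoids import cycle

    rng = np.random.default_rng(profile.seed if seed is None else seed)
    genes = list(profile.gene_means)
    mu_c = np.array([profile.gene_means[g] for g in genes])
    lfc = np.zeros(len(genes))
    planted = dict(profile.planted_de)
    for i, g in enumerate(genes):
        if g in planted:
            lfc[i] = planted[g]
    mu_t = mu_c * np.power(2.0, lfc)

    r = 1.0 / profile.dispersion  # NB size parameter

    def _draw(mu: np.ndarray, n: int) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(len(mu), n))

    counts = np.hstack([_draw(mu_c, profile.n_control), _draw(mu_t, profile.n_treatment)])
    embryos = [f"ctrl_{i + 1}" for i in range(profile.n_control)] + [
        f"treat_{i + 1}" for i in range(profile.n_treatment)
    ]
    conditions = pd.Series(
        ["control"] * profile.n_control + ["treatment"] * profile.n_treatment,
        index=embryos,
        name="condition",
    )
    table = EmbryoCountTable(
        counts=pd.DataFrame(counts, index=genes, columns=embryos),
        gene_lengths=pd.Series(profile.gene_lengths, name="length").reindex(genes),
        conditions=conditions,
        stage=profile.stage,
        groups=dict(profile.groups),
        planted=pd.DataFrame(
            {"gene": list(planted), "log2fc": [planted[g] for g in planted]}
        ),
    )
    return table


# ---------------------------------------------------------------------------
# profile YAML round-trip


def profile_to_yaml(profile: CompositionProfile, path: Path) -> Path:
    data = {
        "name": profile.name,
        "class_fractions": profile.class_fractions,
        "fragment_model": {
            "five_prime_fraction": profile.fragment_model.five_prime_fraction,
            "half_length_mean": profile.fragment_model.half_length_mean,
            "half_length_sd": profile.fragment_model.half_length_sd,
            "short_length_mean": profile.fragment_model.short_length_mean,
            "short_length_sd": profile.fragment_model.short_length_sd,
            "long_mode_weight": profile.fragment_model.long_mode_weight,
            "isoacceptor_weights": profile.fragment_model.isoacceptor_weights,
        },
        "rrna_model": {
            "length_mean": profile.rrna_model.length_mean,
            "length_sd": profile.rrna_model.length_sd,
        },
        "sirna_model": {
            "length_weights": profile.sirna_model.length_weights,
            "five_prime_g_prob": profile.sirna_model.five_prime_g_prob,
        },
        "read_count": profile.read_count,
        "seed": profile.seed,
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


def profile_from_yaml(path: Path) -> CompositionProfile:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CompositionProfile(
        name=data["name"],
        class_fractions=data["class_fractions"],
        fragment_model=FragmentModel(**data["fragment_model"]),
        rrna_model=RRNAFragModel(**data.get("rrna_model", {})),
        sirna_model=SiRNAModel(
            length_weights={int(k): v for k, v in data["sirna_model"]["length_weights"].items()},
            five_prime_g_prob=data["sirna_model"]["five_prime_g_prob"],
        )
        if "sirna_model" in data
        else SiRNAModel(),
        read_count=int(data["read_count"]),
        seed=int(data["seed"]),
    )
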