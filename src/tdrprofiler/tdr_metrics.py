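"""tDR-specific summaries: length x first-nucleotide matrices, 5'/3' half
fractions, per-isoacceptor coverage profiles, and >30 / <=30 nt size splits.

The 5'/3' call splits each mature tRNA at the central anticodon position:
a read belongs to the side holding the strict majority of its aligned
positions (exact tie -> 5').  A read of exactly 30 nt is "short": long means
>= 31 nt, matching the convention that tRNA-halves are the >30 nt species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .classify import ReadAssignment
from .index import SequenceIndex
from .reference import MatureTRNA, ReferenceSet

LENGTH_RANGE = range(18, 41)
NUCLEOTIDES = ("A", "C", "G", "T")

LONG_MIN = 31  # tRNA-half regime; 30 nt and below is the trimmed-fragment regime


def length_firstnt_matrix(
    assignments: Iterable[ReadAssignment], scope: str = "all"
) -> pd.DataFrame:
    """Read counts by (length 18..40, first nucleotide), per-read weight 1.

    scope: 'all' reads, or reads assigned to the 'tRNA' / 'rRNA' class.
    """
    if scope not in ("all", "tRNA", "rRNA"):
        raise ValueError(f"unknown scope {scope!r}")
    mat = pd.DataFrame(0.0, index=list(LENGTH_RANGE), columns=list(NUCLEOTIDES))
    for a in assignments:
        if scope != "all" and a.class_label != scope:
            continue
        if a.read_length in mat.index and a.first_nt in NUCLEOTIDES:
            mat.at[a.read_length, a.first_nt] += 1.0
    return mat


def assign_half(trna: MatureTRNA, start: int, length: int) -> str:
    """5'/3' label of a read aligned at (1-based) start with given length."""
    end = start + length - 1
    if start < 1 or end > trna.length:
        raise ValueError(
            f"read at {start}..{end} outside mature tRNA {trna.trna_id} (1..{trna.length})"
        )
    split = trna.anticodon_start + 1  # central anticodon position
    five_side = max(0, min(end, split - 1) - start + 1)
    three_side = max(0, end - max(start, split + 1) + 1)
    return "three_prime" if three_side > five_side else "five_prime"


@dataclass
class HalfFractions:
    five_prime_pct: float
    three_prime_pct: float
    n_reads: float  # weighted tRNA-assigned read count


def _trna_lookup(refset: ReferenceSet) -> Dict[str, MatureTRNA]:
    return {t.trna_id: t for t in refset.trnas}


def half_fractions(
    assignments: Iterable[ReadAssignment], refset: ReferenceSet
) -> HalfFractions:
    """Weighted percentage of tRNA-mapping reads on each side of the anticodon."""
    lookup = _trna_lookup(refset)
    five = three = 0.0
    for a in assignments:
        if a.class_label != "tRNA":
            continue
        for t in a.targets:
            side = assign_half(lookup[t.record_id], t.start, a.read_length)
            if side == "five_prime":
                five += t.weight
            else:
                three += t.weight
    n = five + three
    if n == 0:
        return HalfFractions(float("nan"), float("nan"), 0.0)
    return HalfFractions(100.0 * five / n, 100.0 * three / n, n)


@dataclass
class CoverageProfile:
    isoacceptor: str
    depth: np.ndarray  # weighted coverage per mature position

    @property
    def total(self) -> float:
        return float(self.depth.sum())


def coverage_profile(
    assignments: Iterable[ReadAssignment],
    refset: ReferenceSet,
    isoacceptor: str,
    index: Optional[SequenceIndex] = None,
) -> CoverageProfile:
    """Per-position weighted read depth across one isoacceptor family.

    Member isodecoders are summed positionally.  When member lengths differ
    by <= 2 nt they are right-aligned at the CCA end; larger differences use
    the longest member's axis with shorter members left-aligned.
    """
    members = [t for t in refset.trnas if t.isoacceptor == isoacceptor]
    if not members:
        raise KeyError(f"unknown isoacceptor {isoacceptor!r}")
    # a collapsed index representative may stand in for several members
    rep_of: Dict[str, str] = {}
    if index is not None:
        for rep, ids in index.trna_members.items():
            for tid in ids:
                rep_of[tid] = rep
    member_ids = {t.trna_id for t in members}
    rep_ids = {rep_of.get(t.trna_id, t.trna_id) for t in members}
    axis_len = max(t.length for t in members)
    small_spread = axis_len - min(t.length for t in members) <= 2
    lookup = _trna_lookup(refset)
    depth = np.zeros(axis_len)
    for a in assignments:
        if a.class_label != "tRNA":
            continue
        for t in a.targets:
            if t.record_id not in member_ids and t.record_id not in rep_ids:
                continue
            trna = lookup[t.record_id]
            offset = (axis_len - trna.length) if small_spread else 0
            lo = t.start - 1 + offset
            depth[lo : lo + a.read_length] += t.weight
    return CoverageProfile(isoacceptor=isoacceptor, depth=depth)


def size_split(
    assignments: Iterable[ReadAssignment],
    refset: ReferenceSet,
    grouping: str = "isodecoder",
) -> pd.DataFrame:
    """Per-tRNA long (>=31 nt) vs short (<=30 nt) weighted counts and rpm.

    rpm denominator is the total tRNA-mapping weight (per-class
    normalization).  grouping: 'isodecoder' (per mature record) or
    'isoacceptor' (family sums).
    """
    if grouping not in ("isodecoder", "isoacceptor"):
        raise ValueError(f"unknown grouping {grouping!r}")
    lookup = _trna_lookup(refset)
    rows: Dict[str, List[float]] = {}
    total = 0.0
    for a in assignments:
        if a.class_label != "tRNA":
            continue
        for t in a.targets:
            key = t.record_id if grouping == "isodecoder" else lookup[t.record_id].isoacceptor
            bucket = rows.setdefault(key, [0.0, 0.0])
            if a.read_length >= LONG_MIN:
                bucket[0] += t.weight
            else:
                bucket[1] += t.weight
            total += t.weight
    if total == 0:
        raise ValueError("no tRNA-mapping reads; rpm denominator is zero")
    df = pd.DataFrame(
        [(k, v[0], v[1]) for k, v in sorted(rows.items())],
        columns=[grouping, "long_count", "short_count"],
    )
    df["long_rpm"] = 1e6 * df["long_count"] / total
    df["short_rpm"] = 1e6 * df["short_count"] / total
    return df


def plot_length_firstnt(matrix: pd.DataFrame, ax=None):
    """Diverging horizontal bar plot: length on y, stacked by first nucleotide."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    left = np.zeros(len(matrix))
    for nt, color in zip(NUCLEOTIDES, ("#4daf4a", "#377eb8", "#ff7f00", "#e41a1c")):
        ax.barh(matrix.index, matrix[nt], left=left, color=color, label=nt)
        left += matrix[nt].to_numpy()
    ax.set_xlabel("reads")
    ax.set_ylabel("read length (nt)")
    ax.legend(title="first nt", fontsize=8)
    return ax


def plot_coverage(profile: CoverageProfile, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.fill_between(np.arange(1, len(profile.depth) + 1), profile.depth, step="mid")
    ax.set_xlabel("mature tRNA position")
    ax.set_ylabel("read depth")
    ax.set_title(profile.isoacceptor)
    return ax
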