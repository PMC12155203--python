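"""Packaged composition and expression profiles.

These fixtures encode the study conditions the pipeline is exercised
against: whole-male and purified-sperm small-RNA libraries from wild-type
and RNaseT2 (rnst-2) mutant worms, and 2-cell / 8-cell single-embryo
experiments with planted differential expression.  tDR class fractions and
5'-half fractions are the headline quantities (sperm 13.8% tDR with a 62%
5' skew; whole males 3.3% / 56%; rnst-2 deletion males 8.6% / 86% against
heterozygous 3.5% / 62.3%; heterozygous females 2.2% with long, >30 nt tDRs
dominating).  Remaining parameters — length means/SDs, the rRNA degradation
skew, the non-tDR class split, NB dispersion — are fixture choices set so
that recovery power is essentially 1; see docs/methods.md.
"""

from __future__ import annotations

import math
from typing import Dict, List

import numpy as np

from .simulate import (
    CompositionProfile,
    ExpressionProfile,
    FragmentModel,
    RRNAFragModel,
    SiRNAModel,
)

# 5' tDRs are dominated by Gly-GCC and Glu-CTC; Ser-AGA carries a 3' bias
_SPERM_ISO_WEIGHTS = {
    "Gly-GCC": 0.30,
    "Glu-CTC": 0.25,
    "Ser-AGA": 0.15,
    "His-GTG": 0.08,
    "Lys-CTT": 0.07,
    "Val-AAC": 0.06,
    "Ala-AGC": 0.05,
    "Asp-GTC": 0.04,
}

_PROFILE_SPECS: Dict[str, dict] = {
    # name: (class fractions, five_prime_fraction, long_mode_weight)
    "wt_sperm": {
        "fractions": {
            "rRNA_frag": 0.25,
            "tDR": 0.138,
            "miRNA": 0.07,
            "piRNA": 0.03,
            "endo_siRNA": 0.302,
            "mRNA_frag": 0.21,
        },
        "five_prime": 0.62,
        "long_mode": 0.60,
    },
    "wt_male": {
        "fractions": {
            "rRNA_frag": 0.20,
            "tDR": 0.033,
            "miRNA": 0.15,
            "piRNA": 0.06,
            "endo_siRNA": 0.40,
            "mRNA_frag": 0.157,
        },
        "five_prime": 0.56,
        "long_mode": 0.35,
    },
    "rnst2_del_male": {
        "fractions": {
            "rRNA_frag": 0.30,
            "tDR": 0.086,
            "miRNA": 0.12,
            "piRNA": 0.05,
            "endo_siRNA": 0.30,
            "mRNA_frag": 0.144,
        },
        "five_prime": 0.86,
        "long_mode": 0.80,
    },
    "rnst2_het_male": {
        "fractions": {
            "rRNA_frag": 0.22,
            "tDR": 0.035,
            "miRNA": 0.14,
            "piRNA": 0.06,
            "endo_siRNA": 0.38,
            "mRNA_frag": 0.165,
        },
        "five_prime": 0.623,
        "long_mode": 0.30,
    },
    "rnst2_het_female": {
        "fractions": {
            "rRNA_frag": 0.22,
            "tDR": 0.022,
            "miRNA": 0.13,
            "piRNA": 0.08,
            "endo_siRNA": 0.42,
            "mRNA_frag": 0.128,
        },
        "five_prime": 0.60,
        "long_mode": 0.85,
    },
}

COMPOSITION_PROFILES = tuple(_PROFILE_SPECS)


def composition_profile(name: str, read_count: int = 200_000, seed: int = 1) -> CompositionProfile:
    """One of the packaged library profiles by name."""
    if name not in _PROFILE_SPECS:
        raise KeyError(f"unknown profile {name!r}; choose from {COMPOSITION_PROFILES}")
    spec = _PROFILE_SPECS[name]
    return CompositionProfile(
        name=name,
        class_fractions=dict(spec["fractions"]),
        fragment_model=FragmentModel(
            five_prime_fraction=spec["five_prime"],
            long_mode_weight=spec["long_mode"],
            isoacceptor_weights=dict(_SPERM_ISO_WEIGHTS),
        ),
        rrna_model=RRNAFragModel(length_mean=21.0, length_sd=3.0),
        sirna_model=SiRNAModel(),
        read_count=read_count,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expression fixtures

_N_GENES = 6000
_GENE_UNIVERSE_SEED = 777  # gene names/means/lengths are a fixed fixture


def _gene_universe():
    """Deterministic ~6000-gene universe with named functional groups."""
    rng = np.random.default_rng(_GENE_UNIVERSE_SEED)
    names: List[str] = []
    names += [f"his-{i}" for i in range(1, 41)]  # canonical histones
    names += [f"fbxb-{i}" for i in range(1, 31)]
    names += [f"hsp-{i}" for i in range(1, 21)]
    names += [f"rpl-{i}" for i in range(1, 31)] + [f"rps-{i}" for i in range(1, 31)]
    names += ["ife-2"]
    n_other = _N_GENES - len(names)
    names += [f"g{i:04d}" for i in range(1, n_other + 1)]
    # baseline means: unnamed genes span ~2.5 orders of magnitude; the named
    # functional groups (histones, ribosomal proteins, ...) sit in the
    # well-expressed range, as they do in early embryos
    n_named = _N_GENES - n_other
    means = np.concatenate(
        [
            10.0 ** rng.uniform(2.5, 4.0, size=n_named),
            10.0 ** rng.uniform(1.5, 4.0, size=n_other),
        ]
    )
    lengths = rng.integers(500, 3001, size=_N_GENES)
    groups = {
        "histone": [n for n in names if n.startswith("his-")],
        "fbxb": [n for n in names if n.startswith("fbxb-")],
        "hsp": [n for n in names if n.startswith("hsp-")],
        "ribosomal": [n for n in names if n.startswith(("rpl-", "rps-"))],
    }
    gene_means = dict(zip(names, means))
    gene_lengths = {n: int(l) for n, l in zip(names, lengths)}
    return names, gene_means, gene_lengths, groups


def expression_profile(stage: str, seed: int = 1) -> ExpressionProfile:
    """Packaged single-embryo profiles.

    ``two_cell``: 36 genes planted up (ife-2 at 2.5-fold, the rest at
    4-fold) and 2 down, compared across 30 control vs 25 treatment embryos.
    ``eight_cell``: 106 genes planted down (33 histone, 15 fbxb, 58 other)
    and 16 up, 20 vs 26 embryos.  ``two_cell_null`` has no planted effects
    (type-I calibration).  ``eight_cell_rescue`` plants the same genes in the
    same directions as ``eight_cell`` (a rescue comparison reproduces the
    shifts).
    """
    names, gene_means, gene_lengths, groups = _gene_universe()
    rng = np.random.default_rng(_GENE_UNIVERSE_SEED + 1)  # planted-gene picks are fixed
    # plant effects in confidently quantifiable genes (>~300 mean counts)
    other = [n for n in names if n.startswith("g") and gene_means[n] >= 300.0]
    pick = rng.permutation(len(other))

    planted: List[tuple] = []
    if stage in ("two_cell", "two_cell_rescue"):
        planted.append(("ife-2", math.log2(2.5)))
        up = [other[i] for i in pick[:35]]
        down = [other[i] for i in pick[35:37]]
        planted += [(g, 2.0) for g in up] + [(g, -2.0) for g in down]
        n_control, n_treatment = 30, 25
    elif stage in ("eight_cell", "eight_cell_rescue"):
        down = groups["histone"][:33] + groups["fbxb"][:15] + [other[i] for i in pick[:58]]
        up = [other[i] for i in pick[58:74]]
        planted += [(g, -2.0) for g in down] + [(g, 2.0) for g in up]
        n_control, n_treatment = 20, 26
    elif stage in ("two_cell_null", "eight_cell_null"):
        n_control, n_treatment = 30, 25
    else:
        raise KeyError(f"unknown expression profile {stage!r}")

    return ExpressionProfile(
        stage=stage,
        gene_means=gene_means,
        gene_lengths=gene_lengths,
        groups=groups,
        planted_de=planted,
        dispersion=0.02,
        n_control=n_control,
        n_treatment=n_treatment,
        seed=seed,
    )
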