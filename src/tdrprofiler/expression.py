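"""Single-embryo differential expression and gene-group shift analysis.

Counts are TPM-normalized (length-corrected, columns sum to 1e6).  The DE
caller computes per-gene log2 fold changes of condition mean TPM (with a
pseudocount) and a Welch two-tailed t-test on log2(TPM + 1); a gene is
flagged up when log2FC > 1 and P <= 0.01, down when log2FC < -1 and
P <= 0.01 — deliberately a raw-P threshold rule, no multiple-testing
correction by default.  Coordinated regulation of a gene family (histones,
fbxb, hsp, ribosomal proteins) is assessed by comparing the family's
log2FC distribution against all remaining genes with a two-sample
Kolmogorov-Smirnov test and empirical CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EmbryoCountTable:
    """Genes x embryos integer counts with lengths and condition labels."""

    counts: pd.DataFrame
    gene_lengths: pd.Series
    conditions: pd.Series
    stage: str = ""
    groups: Dict[str, List[str]] = field(default_factory=dict)
    planted: Optional[pd.DataFrame] = None  # truth set from the simulator

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.gene_lengths.index.equals(self.counts.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        vc = self.conditions.value_counts()
        if (vc < 2).any():
            raise ValueError("need at least 2 embryos per condition")

    def to_tsv(self, path: Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"#stage={self.stage}\n")
            fh.write("#condition\t\t" + "\t".join(self.conditions[c] for c in self.counts.columns) + "\n")
            out = self.counts.copy()
            out.insert(0, "length", self.gene_lengths)
            out.index.name = "gene_id"
            out.to_csv(fh, sep="\t")
        return path

    @classmethod
    def from_tsv(cls, path: Path) -> "EmbryoCountTable":
        path = Path(path)
        with open(path) as fh:
            stage_line = fh.readline().strip()
            cond_line = fh.readline().rstrip("\n")
            df = pd.read_csv(fh, sep="\t", index_col=0)
        stage = stage_line.split("=", 1)[1] if "=" in stage_line else ""
        cond_values = cond_line.split("\t")[2:]
        lengths = df["length"]
        counts = df.drop(columns=["length"])
        conditions = pd.Series(cond_values, index=counts.columns, name="condition")
        return cls(counts=counts, gene_lengths=lengths, conditions=conditions, stage=stage)


def tpm_normalize(table: EmbryoCountTable) -> pd.DataFrame:
    """TPM per embryo: 1e6 * (count/length) / sum(count/length)."""
    rate = table.counts.div(table.gene_lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"embryo {zero.index[0]!r} has zero total counts")
    return 1e6 * rate.div(totals, axis=1)


def differential_expression(
    tpm: pd.DataFrame,
    conditions: pd.Series,
    cond_a: str,
    cond_b: str,
    lfc_cut: float = 1.0,
    p_cut: float = 0.01,
    pseudocount: float = 1.0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene DE of cond_b vs cond_a (positive log2FC = higher in cond_b).

    Returns columns mean_a, mean_b, log2fc, pval, flag (up/down/ns).  With
    ``bh_correct`` the flag threshold applies to Benjamini-Hochberg adjusted
    p-values (off by default: the flag rule mirrors a raw-P <= 0.01 cut).
    """
    a_cols = conditions.index[conditions == cond_a]
    b_cols = conditions.index[conditions == cond_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least 2 embryos in each condition")
    xa = tpm[a_cols].to_numpy()
    xb = tpm[b_cols].to_numpy()
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    la = np.log2(xa + pseudocount)
    lb = np.log2(xb + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pval = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    # zero-variance degeneracy: identical groups get p=1, separated ones p=0
    nan = np.isnan(pval)
    if nan.any():
        same = np.isclose(lb.mean(axis=1), la.mean(axis=1))
        pval = np.where(nan, np.where(same, 1.0, 0.0), pval)
    p_for_flag = pval
    out = pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc, "pval": pval},
        index=tpm.index,
    )
    if bh_correct:
        out["padj"] = _benjamini_hochberg(pval)
        p_for_flag = out["padj"].to_numpy()
    flag = np.where(
        (log2fc > lfc_cut) & (p_for_flag <= p_cut),
        "up",
        np.where((log2fc < -lfc_cut) & (p_for_flag <= p_cut), "down", "ns"),
    )
    out["flag"] = flag
    return out


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class GroupShift:
    group: str
    members: List[str]
    median_log2fc: float
    background_median: float
    ks_statistic: float
    ks_pvalue: float
    group_cdf: Tuple[np.ndarray, np.ndarray]  # (sorted log2FC, ecdf)
    background_cdf: Tuple[np.ndarray, np.ndarray]


def _ecdf(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    return x, np.arange(1, len(x) + 1) / len(x)


def group_shift(de: pd.DataFrame, group_genes: Iterable[str], name: str = "group") -> GroupShift:
    """Distributional shift of a gene family's log2FC vs all remaining genes."""
    members = [g for g in group_genes if g in de.index]
    if not members:
        raise ValueError(f"group {name!r} has no members among expressed genes")
    background = de.index.difference(members)
    if len(background) == 0:
        raise ValueError("group covers all genes; empty background")
    gvals = de.loc[members, "log2fc"].to_numpy()
    bvals = de.loc[background, "log2fc"].to_numpy()
    ks = stats.ks_2samp(gvals, bvals)
    return GroupShift(
        group=name,
        members=members,
        median_log2fc=float(np.median(gvals)),
        background_median=float(np.median(bvals)),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        group_cdf=_ecdf(gvals),
        background_cdf=_ecdf(bvals),
    )


def rescue_comparison(
    de_mut_vs_wt: pd.DataFrame,
    de_ctrl_vs_rescue: pd.DataFrame,
    groups: Optional[Dict[str, List[str]]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Paired fold-change table for a rescue experiment.

    x = log2FC of mutant-sired vs WT-sired embryos, y = log2FC of control
    vs rescue-treated embryos.  Genes in the lower-left and upper-right
    quadrants respond the same way in both comparisons (concordant =
    rescued expression change).  Returns (per-gene table, per-group
    concordance summary).
    """
    shared = de_mut_vs_wt.index.intersection(de_ctrl_vs_rescue.index)
    if len(shared) == 0:
        raise ValueError("the two DE results share no genes")
    pairs = pd.DataFrame(
        {
            "x_log2fc": de_mut_vs_wt.loc[shared, "log2fc"],
            "y_log2fc": de_ctrl_vs_rescue.loc[shared, "log2fc"],
        },
        index=shared,
    )
    pairs["concordant"] = pairs["x_log2fc"] * pairs["y_log2fc"] > 0
    rows = []
    groups = groups or {}
    for name, genes in groups.items():
        members = shared.intersection(pd.Index(genes))
        if len(members) == 0:
            continue
        conc = int(pairs.loc[members, "concordant"].sum())
        rows.append((name, len(members), conc, conc / len(members)))
    summary = pd.DataFrame(rows, columns=["group", "n_genes", "n_concordant", "fraction"])
    return pairs, summary
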