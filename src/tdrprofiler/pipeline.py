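"""End-to-end orchestration: simulate -> classify -> metrics -> DE -> survival.

run_pipeline drives every stage against the bundled toy reference set and
the packaged profiles, writes stage tables, and returns a machine-readable
summary.  Re-running with the same config is byte-identical; every output
carries the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import classify as _classify
from . import expression as _expr
from . import profiles as _profiles
from . import sirna as _sirna
from . import survival as _surv
from . import tdr_metrics as _metrics
from .index import SequenceIndex
from .simulate import (
    DEFAULT_ADAPTER,
    simulate_embryo_counts,
    simulate_small_rna_reads,
    write_fastq,
    write_truth,
)
from .toyref import toy_reference_set


@dataclass
class RunConfig:
    composition_profiles: List[str] = field(
        default_factory=lambda: list(_profiles.COMPOSITION_PROFILES)
    )
    expression_stages: List[str] = field(default_factory=lambda: ["two_cell", "eight_cell"])
    read_count: int = 200_000
    adapter: str = DEFAULT_ADAPTER
    mismatches: int = 0
    normalization: str = "genome"
    lfc_cut: float = 1.0
    p_cut: float = 0.01
    seed: int = 1
    outdir: str = "tdrprofiler_run"

    def __post_init__(self) -> None:
        if self.lfc_cut <= 0 or not (0 < self.p_cut <= 1):
            raise ValueError("thresholds must be positive (p_cut in (0, 1])")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _stamp(path: Path, config: RunConfig) -> None:
    text = path.read_text()
    path.write_text(f"# seed={config.seed} config={config.hash()}\n{text}")


def library_summary(
    profile_name: str,
    config: RunConfig,
    refset=None,
    index: Optional[SequenceIndex] = None,
    write_dir: Optional[Path] = None,
) -> Dict:
    """Simulate one library, classify it, and compute the headline metrics."""
    refset = refset or toy_reference_set()
    index = index or SequenceIndex(refset, config.mismatches)
    profile = _profiles.composition_profile(
        profile_name, read_count=config.read_count, seed=config.seed
    )
    library = simulate_small_rna_reads(profile, refset)
    raw = [_classify.Read(r.read_id, (r.sequence + config.adapter)[:75]) for r in library.reads]
    reads = _classify.trim_and_filter(raw, config.adapter)
    assignments = _classify.classify_reads(reads, index, refset)
    counts = _classify.count_classes(assignments)
    norm = _classify.normalize(counts, config.normalization)
    halves = _metrics.half_fractions(assignments, refset)
    split = _metrics.size_split(assignments, refset, grouping="isoacceptor")
    summary = {
        "profile": profile_name,
        "n_input": counts.total_input,
        "n_genome_mapping": counts.total_genome_mapping,
        "class_pct_of_genome_mapping": {
            label: 100.0 * counts.counts[label] / counts.total_genome_mapping
            for label in _classify.GENOME_MAPPING_LABELS
        },
        "rpm": norm.values,
        "five_prime_pct": halves.five_prime_pct,
        "three_prime_pct": halves.three_prime_pct,
        "n_trna_reads": halves.n_reads,
    }
    if write_dir is not None:
        write_dir.mkdir(parents=True, exist_ok=True)
        write_fastq(library, write_dir / f"{profile_name}.fastq", with_adapter=True)
        write_truth(library, write_dir / f"{profile_name}.truth.tsv")
        df = _classify.assignments_to_frame(assignments)
        p = write_dir / f"{profile_name}.assignments.tsv"
        df.to_csv(p, sep="\t", index=False)
        _stamp(p, config)
        p = write_dir / f"{profile_name}.size_split.tsv"
        split.to_csv(p, sep="\t", index=False)
        _stamp(p, config)
        sir = _sirna.per_gene_antisense_counts(assignments, counts)
        p = write_dir / f"{profile_name}.sirna.tsv"
        sir.to_csv(p, sep="\t", index=False)
        _stamp(p, config)
    return summary


def expression_summary(stage: str, config: RunConfig, write_dir: Optional[Path] = None) -> Dict:
    profile = _profiles.expression_profile(stage, seed=config.seed)
    table = simulate_embryo_counts(profile)
    tpm = _expr.tpm_normalize(table)
    de = _expr.differential_expression(
        tpm, table.conditions, "control", "treatment",
        lfc_cut=config.lfc_cut, p_cut=config.p_cut,
    )
    shifts = {}
    for name, genes in table.groups.items():
        gs = _expr.group_shift(de, genes, name=name)
        shifts[name] = {
            "median_log2fc": gs.median_log2fc,
            "ks_statistic": gs.ks_statistic,
            "ks_pvalue": gs.ks_pvalue,
        }
    summary = {
        "stage": stage,
        "n_genes": int(len(de)),
        "n_up": int((de["flag"] == "up").sum()),
        "n_down": int((de["flag"] == "down").sum()),
        "group_shifts": shifts,
    }
    if write_dir is not None:
        write_dir.mkdir(parents=True, exist_ok=True)
        table.to_tsv(write_dir / f"{stage}.counts.tsv")
        p = write_dir / f"{stage}.de.tsv"
        de.to_csv(p, sep="\t")
        _stamp(p, config)
    return summary


def survival_demo(config: RunConfig) -> Dict:
    """Synthetic two-group starvation survival + heat-shock plate example."""
    rng = np.random.default_rng(config.seed)
    t_a = rng.exponential(10.0, size=60).round() + 1
    t_b = rng.exponential(6.0, size=60).round() + 1
    data = pd.DataFrame(
        {
            "time": np.concatenate([t_a, t_b]),
            "event": 1,
            "group": ["control"] * 60 + ["mutant_sired"] * 60,
        }
    )
    chi2, p = _surv.logrank_test(data, "control", "mutant_sired")
    plates = pd.DataFrame(
        {
            "group": ["control"] * 3 + ["anti_tdr"] * 3,
            "n_scored": [50] * 6,
            "n_alive": list(rng.binomial(50, 0.45, size=3)) + list(rng.binomial(50, 0.75, size=3)),
        }
    )
    tt = _surv.proportion_ttest(plates, "control", "anti_tdr")
    km = _surv.km_estimate(data, group="control")
    return {
        "logrank_chi2": chi2,
        "logrank_p": p,
        "km_median_survival_control": float(
            km.loc[km["survival"] <= 0.5, "time"].min()
        ),
        "heat_shock_t": tt.t_statistic,
        "heat_shock_p": tt.pvalue,
    }


def run_pipeline(config: RunConfig) -> Dict:
    """Run every stage; returns (and writes) the JSON summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refset = toy_reference_set()
    index = SequenceIndex(refset, config.mismatches)
    summary: Dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "libraries": {},
        "expression": {},
    }
    for name in config.composition_profiles:
        try:
            summary["libraries"][name] = library_summary(
                name, config, refset=refset, index=index, write_dir=outdir
            )
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            raise RuntimeError(f"library stage failed for profile {name!r}: {exc}") from exc
    for stage in config.expression_stages:
        try:
            summary["expression"][stage] = expression_summary(stage, config, write_dir=outdir)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"expression stage failed for {stage!r}: {exc}") from exc
    try:
        summary["survival"] = survival_demo(config)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"survival stage failed: {exc}") from exc
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
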