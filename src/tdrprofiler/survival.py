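"""Survival statistics for inheritance phenotypes.

Kaplan-Meier product-limit curves with Greenwood log-log 95% confidence
intervals and the standard 1-df log-rank test cover starvation-survival
comparisons; replicate-plate survival proportions after heat shock are
compared with a Welch two-tailed t-test.  Plate-level daily counts can be
converted to pseudo-individual records (each death becomes an event at its
observation day; animals alive at the final day are censored there).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def km_estimate(
    data: pd.DataFrame, group: Optional[str] = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Product-limit survival estimate.

    ``data`` has columns time, event (1=death, 0=censored) and optionally
    group; rows are individual observations.  Returns one row per distinct
    event time: n_at_risk, n_events, survival, ci_lower, ci_upper.
    """
    df = data if group is None else data[data["group"] == group]
    if len(df) == 0:
        raise ValueError(f"no observations{'' if group is None else f' in group {group!r}'}")
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    if (times < 0).any():
        raise ValueError("negative times")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    z = stats.norm.ppf(1 - alpha / 2)

    rows = []
    s = 1.0
    greenwood = 0.0  # running sum d / (n (n - d))
    n_total = len(times)
    for t in np.unique(times[events == 1]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            greenwood += d / (n_at_risk * (n_at_risk - d))
        if 0.0 < s < 1.0:
            # log(-log S) transform keeps the interval inside [0, 1]
            se = np.sqrt(greenwood) / abs(np.log(s))
            lo = s ** np.exp(z * se)
            hi = s ** np.exp(-z * se)
        else:
            lo = hi = s
        rows.append((t, n_at_risk, d, s, lo, hi))
    out = pd.DataFrame(
        rows, columns=["time", "n_at_risk", "n_events", "survival", "ci_lower", "ci_upper"]
    )
    out.attrs["n_observations"] = n_total
    return out


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """S(t) from a km_estimate table (right-continuous step function)."""
    past = km[km["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def logrank_test(data: pd.DataFrame, group_a: str, group_b: str) -> Tuple[float, float]:
    """Standard 1-df log-rank chi-square and p for two groups.

    Uses the hypergeometric variance at each distinct event time; no
    additional ties correction.
    """
    sub = data[data["group"].isin([group_a, group_b])]
    if (sub["group"] == group_a).sum() == 0 or (sub["group"] == group_b).sum() == 0:
        raise ValueError("both groups must be non-empty")
    if (sub["event"] == 1).sum() == 0:
        raise ValueError("log-rank needs at least one event")
    times = sub["time"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    is_a = (sub["group"] == group_a).to_numpy()

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & is_a).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d1 = int((dying & is_a).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class ProportionTestResult:
    t_statistic: float
    pvalue: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def proportion_ttest(
    plates: pd.DataFrame, group_a: str, group_b: str
) -> ProportionTestResult:
    """Welch two-tailed t-test on per-plate survival proportions.

    ``plates`` has columns group, n_scored, n_alive; each row is one
    replicate plate.  Identical zero-variance groups get p=1 by convention.
    """
    def props(g: str) -> np.ndarray:
        sub = plates[plates["group"] == g]
        if len(sub) < 2:
            raise ValueError(f"group {g!r} needs at least 2 plates")
        if ((sub["n_alive"] < 0) | (sub["n_alive"] > sub["n_scored"])).any():
            raise ValueError("n_alive must lie in [0, n_scored]")
        return (sub["n_alive"] / sub["n_scored"]).to_numpy(dtype=float)

    pa, pb = props(group_a), props(group_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(pa, pb, equal_var=False)
    if np.isnan(p):
        t, p = 0.0, 1.0
        if not np.isclose(pa.mean(), pb.mean()):
            t, p = np.inf, 0.0
    return ProportionTestResult(
        t_statistic=float(t),
        pvalue=float(p),
        mean_a=float(pa.mean()),
        sd_a=float(pa.std(ddof=1)),
        mean_b=float(pb.mean()),
        sd_b=float(pb.std(ddof=1)),
    )


def plates_to_individuals(daily: pd.DataFrame) -> pd.DataFrame:
    """Expand plate-level daily counts to pseudo-individual survival records.

    ``daily`` has columns day, group, n_dead (deaths observed that day) and
    n_alive (animals alive after scoring).  Deaths become events at their
    day; animals alive at the last scored day are censored there.
    """
    rows = []
    for grp, sub in daily.groupby("group"):
        sub = sub.sort_values("day")
        for r in sub.itertuples():
            rows += [(float(r.day), 1, grp)] * int(r.n_dead)
        last = sub.iloc[-1]
        rows += [(float(last["day"]), 0, grp)] * int(last["n_alive"])
    return pd.DataFrame(rows, columns=["time", "event", "group"])


def plot_km(km: pd.DataFrame, ax=None, label: Optional[str] = None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = np.concatenate([[0.0], km["time"].to_numpy()])
    s = np.concatenate([[1.0], km["survival"].to_numpy()])
    ax.step(t, s, where="post", label=label)
    if len(km):
        ax.fill_between(
            km["time"], km["ci_lower"], km["ci_upper"], step="post", alpha=0.2
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("fraction surviving")
    ax.set_ylim(0, 1.05)
    return ax
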