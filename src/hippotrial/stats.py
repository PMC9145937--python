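"""Endpoint extraction and the trial's statistical battery.

Endpoints per simulation and region (over the principal cells of the
region -- granule in DG, pyramidal in CA3/CA1):

* number of spikes: sum over cells;
* mean interspike interval (CA1): mean over cells of the within-cell
  mean ISI, cells with >= 2 spikes;
* frequency (CA1): mean over cells of spike count / duration.

The battery mirrors a standard parametric workup: arithmetic means
with 95% t confidence intervals, Shapiro-Wilk normality per group,
Brown-Forsythe (median-centred Levene) homogeneity of variance,
one-way ANOVA with Tukey's HSD post hoc, and Pearson correlation.
Box-whisker plots use mean (midline), mean +/- SE (box) and the 95%
CI (whiskers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .engine import SpikeRecord

ENDPOINTS = ("n_spikes", "mean_isi", "frequency")
ALPHA = 0.05


@dataclass
class EndpointVector:
    values: np.ndarray
    endpoint: str                  # n_spikes | mean_isi | frequency
    region: str
    arm: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")


@dataclass
class ComparisonTable:
    """One omnibus comparison with its assumptions and post hocs."""

    anova_F: float
    anova_p: float
    tukey: pd.DataFrame            # group1, group2, meandiff, p_adj, reject
    group_means: pd.DataFrame      # arm, n, mean, ci_lower, ci_upper
    shapiro_p: dict                # arm -> p
    brown_forsythe_p: float


def count_spikes(record: SpikeRecord, region: str) -> int:
    """Total spikes over the principal cells of a region."""
    cells = record.cells(region)
    if not cells:
        raise ValueError(f"region {region!r} has no principal cells")
    return int(sum(len(record.spike_times[c]) for c in cells))


def isi_and_frequency(record: SpikeRecord, region: str = "CA1"
                      ) -> tuple[float, float]:
    """(mean ISI seconds, mean per-cell frequency Hz) of a region.

    ISI is the mean over cells of the within-cell mean interval
    (cells with >= 2 spikes); nan when no cell qualifies.  Frequency
    averages count/duration over all principal cells of the region.
    """
    cells = record.cells(region)
    if not cells:
        raise ValueError(f"region {region!r} has no principal cells")
    isis = [float(np.mean(np.diff(record.spike_times[c])))
            for c in cells if len(record.spike_times[c]) >= 2]
    mean_isi = float(np.mean(isis)) if isis else float("nan")
    freq = float(np.mean([len(record.spike_times[c]) / record.duration
                          for c in cells]))
    return mean_isi, freq


def mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Arithmetic mean with a t-distribution confidence interval."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    m = float(np.mean(x))
    if level <= 0:
        return m, m, m
    half = (sps.t.ppf(0.5 + level / 2, x.size - 1)
            * np.std(x, ddof=1) / math.sqrt(x.size))
    return m, m - float(half), m + float(half)


def anova_tukey(groups: list[EndpointVector]) -> ComparisonTable:
    """One-way ANOVA with Tukey HSD across arms, plus assumption checks."""
    if len(groups) < 2 or any(g.values.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    arrays = [g.values for g in groups]
    labels = [g.arm or f"group{i}" for i, g in enumerate(groups)]

    if all(np.ptp(a) == 0 for a in arrays):
        f_stat, p = float("nan"), float("nan")
    elif all(np.allclose(a, arrays[0]) for a in arrays):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*arrays)

    flat = np.concatenate(arrays)
    lab = np.concatenate([[l] * a.size for l, a in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(flat, lab, alpha=ALPHA)
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=[c.strip() for c in tk.summary().data[0]])
    tukey = tukey.rename(columns={"p-adj": "p_adj"})

    rows = []
    for l, a in zip(labels, arrays):
        m, lo, hi = mean_ci(a)
        rows.append({"arm": l, "n": a.size, "mean": m,
                     "ci_lower": lo, "ci_upper": hi})
    shapiro = {l: (float(sps.shapiro(a).pvalue) if a.size >= 3
                   and np.ptp(a) > 0 else float("nan"))
               for l, a in zip(labels, arrays)}
    try:
        bf = float(sps.levene(*arrays, center="median").pvalue)
    except Exception:
        bf = float("nan")
    return ComparisonTable(anova_F=float(f_stat), anova_p=float(p),
                           tukey=tukey, group_means=pd.DataFrame(rows),
                           shapiro_p=shapiro, brown_forsythe_p=bf)


def normality_and_variance_checks(groups: list[EndpointVector]):
    """Per-group Shapiro-Wilk p and across-group Brown-Forsythe p."""
    shapiro = {}
    for i, g in enumerate(groups):
        label = g.arm or f"group{i}"
        if g.values.size < 3 or np.ptp(g.values) == 0:
            shapiro[label] = float("nan")
        else:
            shapiro[label] = float(sps.shapiro(g.values).pvalue)
    bf = float(sps.levene(*[g.values for g in groups],
                          center="median").pvalue)
    return shapiro, bf


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def endpoint_frame(records: dict, duration: float | None = None
                   ) -> pd.DataFrame:
    """Tidy endpoints table from {(hippocampus_id, severity, arm): record}.

    One row per simulation x region with columns hippocampus_id,
    severity, arm, region, n_spikes, mean_isi_s, freq_hz.
    """
    rows = []
    for (hid, severity, arm), rec in records.items():
        for region in ("DG", "CA3", "CA1"):
            isi, freq = isi_and_frequency(rec, region)
            rows.append({"hippocampus_id": hid, "severity": severity,
                         "arm": arm, "region": region,
                         "n_spikes": count_spikes(rec, region),
                         "mean_isi_s": isi, "freq_hz": freq})
    return pd.DataFrame(rows)


def boxplot_endpoints(frame: pd.DataFrame, endpoint: str, region: str,
                      severity: str, path=None):
    """Mean/SE/95%-CI box-whisker figure for one endpoint and region."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = {"n_spikes": "n_spikes", "mean_isi": "mean_isi_s",
           "frequency": "freq_hz"}[endpoint]
    sub = frame[(frame.region == region) & (frame.severity == severity)]
    arms = sorted(sub.arm.unique(), key=lambda a: (a != "placebo", a))
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, arm in enumerate(arms):
        vals = sub[sub.arm == arm][col].dropna().to_numpy()
        if vals.size < 2:
            continue
        m, lo, hi = mean_ci(vals)
        se = np.std(vals, ddof=1) / math.sqrt(vals.size)
        ax.add_patch(plt.Rectangle((i - 0.2, m - se), 0.4, 2 * se,
                                   fill=False))
        ax.plot([i - 0.2, i + 0.2], [m, m], "k-")
        ax.plot([i, i], [lo, hi], "k-", lw=0.8)
        ax.plot([i - 0.1, i + 0.1], [lo, lo], "k-", lw=0.8)
        ax.plot([i - 0.1, i + 0.1], [hi, hi], "k-", lw=0.8)
    ax.set_xticks(range(len(arms)), arms)
    ax.set_ylabel({"n_spikes": "number of spikes", "mean_isi": "ISI (s)",
                   "frequency": "frequency (Hz)"}[endpoint])
    ax.set_title(f"{region}, {severity} AD")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
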