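"""ChIP-signal summarization by compartment and expression group comparisons.

Signal tracks are 1-kb binned coverage vectors (treatment and input, RPM
scale). The per-compartment statistic is the sum over contained 1-kb bins of
log2 fold enrichment (treatment/input) with a pseudocount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import compartment_intervals
from .genome import BinnedGenome

__all__ = [
    "SignalTrack",
    "compartment_signal",
    "peak_counts_by_compartment",
    "compare_expression_groups",
]


@dataclass
class SignalTrack:
    """Genome-wide treatment/input coverage at fixed (1-kb) bins."""

    genome: BinnedGenome
    treatment: dict[str, np.ndarray]
    input_: dict[str, np.ndarray]

    def __post_init__(self):
        for c in self.genome.chrom_names:
            n = self.genome.n_bins(c)
            if len(self.treatment[c]) != n or len(self.input_[c]) != n:
                raise ValueError(f"signal length mismatch on {c}")
            if (self.treatment[c] < 0).any() or (self.input_[c] < 0).any():
                raise ValueError("signal values must be non-negative")


def compartment_signal(
    signal: SignalTrack,
    track,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Summed log2 fold enrichment per compartment interval and per label.

    For each compartment interval, sums log2((treatment + ε)/(input + ε))
    over the 1-kb bins it contains. Returns per-interval rows; the by-label
    aggregate lives in the ``label`` groupby of the result.
    """
    if signal.genome.chrom_names != track.genome.chrom_names or \
            signal.genome.lengths != track.genome.lengths:
        raise ValueError("signal and compartment track are on different genomes")
    ivs = compartment_intervals(track)
    sb = signal.genome.bin_size
    rows = []
    for _, iv in ivs.iterrows():
        c = iv["chrom"]
        b0 = iv["start"] // sb
        b1 = -(-iv["end"] // sb)
        t = signal.treatment[c][b0:b1]
        i = signal.input_[c][b0:b1]
        fe = np.log2((t + pseudocount) / (i + pseudocount))
        rows.append({**iv, "n_bins": b1 - b0, "signal_sum": float(fe.sum())})
    out = pd.DataFrame(rows)
    return out


def aggregate_signal_by_label(per_interval: pd.DataFrame) -> pd.Series:
    return per_interval.groupby("label")["signal_sum"].sum()


def peak_counts_by_compartment(peaks: pd.DataFrame, track) -> pd.DataFrame:
    """Assign each peak to the compartment label of its midpoint bin.

    Returns per-interval counts and densities; totals per label via groupby.
    Peaks whose midpoint falls in a masked bin get label 'masked'.
    """
    ivs = compartment_intervals(track)
    g = track.genome
    rows = []
    for _, iv in ivs.iterrows():
        sub = peaks[peaks["chrom"] == iv["chrom"]]
        mid = (sub["start"] + sub["end"]) // 2
        k = int(((mid >= iv["start"]) & (mid < iv["end"])).sum())
        rows.append({**iv, "n_peaks": k,
                     "density_per_mb": k / ((iv["end"] - iv["start"]) / 1e6)})
    out = pd.DataFrame(rows)
    # account for masked assignments
    assigned = out["n_peaks"].sum() if len(out) else 0
    out.attrs["n_masked"] = int(len(peaks) - assigned)
    return out


def compare_peak_densities(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                           label: str = "A") -> dict:
    """Rank-sum comparison of per-interval peak densities between two tracks."""
    x = counts_a.loc[counts_a["label"] == label, "density_per_mb"]
    y = counts_b.loc[counts_b["label"] == label, "density_per_mb"]
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {"label": label, "statistic": float(stat), "p_value": float(p),
            "median_diff": float(x.median() - y.median())}


def compare_expression_groups(
    expr: pd.Series | pd.DataFrame,
    group_assignment: pd.Series,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum (Wilcoxon/Mann-Whitney) tests on FPKM.

    ``expr`` is a per-gene FPKM vector (one cell type); ``group_assignment``
    a per-gene category. Empty groups are skipped with a warning. Reports the
    median difference (on the log2 scale when ``log_transform``).
    """
    if isinstance(expr, pd.DataFrame):
        raise TypeError("pass a single cell type's FPKM Series")
    common = expr.index.intersection(group_assignment.index)
    x = expr.loc[common].astype(float)
    if log_transform:
        x = np.log2(x + pseudocount)
    grp = group_assignment.loc[common]
    names = [g for g in grp.unique() if (grp == g).sum() > 0]
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups")
    rows = []
    for g1, g2 in combinations(names, 2):
        a, b = x[grp == g1], x[grp == g2]
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"empty group in comparison {g1} vs {g2}; skipped",
                          RuntimeWarning)
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({
            "group1": g1, "group2": g2, "n1": len(a), "n2": len(b),
            "median_diff": float(a.median() - b.median()),
            "statistic": float(stat), "p_value": float(p),
        })
    return pd.DataFrame(rows)
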