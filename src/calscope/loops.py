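"""Chromatin loops, APA scoring, and compartment-associating loops (CALs).

A CAL is a chromatin loop whose two anchors fall inside the *same*
contiguous A/B compartment interval — the loop does not cross a compartment
boundary. CALs inherit the interval's activation/repression class (from
k-means clustering of PC1 profiles): CALs in activation-class intervals are
aCALs, those in repression-class intervals are repressed CALs. Gene sets are
formed from genes overlapping the loop spans of each subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import formats
from .compartments import (ACTIVATION, REPRESSION, CompartmentTrack,
                           compartment_intervals)
from .contacts import ContactMap, MatrixStateError
from .genome import BinnedGenome

__all__ = [
    "LoopSet",
    "CalSet",
    "ApaResult",
    "read_loops_bedpe",
    "write_loops_bedpe",
    "apa_score",
    "genes_in_loops",
    "identify_cals",
    "split_cals_by_class",
    "peak_overlap_test",
]

LOOP_COLS = ["chrom", "start1", "end1", "start2", "end2"]


@dataclass
class LoopSet:
    """Intra-chromosomal anchor pairs, sorted, anchor2 downstream of anchor1."""

    loops: pd.DataFrame  # chrom, start1, end1, start2, end2 (+ extra columns)
    cell_type: str = ""

    def __post_init__(self):
        df = self.loops.reset_index(drop=True)
        if len(df):
            if (df["end1"] <= df["start1"]).any() or (df["end2"] <= df["start2"]).any():
                raise ValueError("anchor with end <= start")
            # orient so anchor1 is upstream; anchors must not overlap
            flip = df["start2"] < df["start1"]
            if flip.any():
                a = df.loc[flip, ["start1", "end1"]].to_numpy()
                df.loc[flip, ["start1", "end1"]] = df.loc[
                    flip, ["start2", "end2"]].to_numpy()
                df.loc[flip, ["start2", "end2"]] = a
            if (df["start2"] < df["end1"]).any():
                raise ValueError("overlapping anchors within a loop")
            df = df.sort_values(["chrom", "start1", "start2"]).reset_index(drop=True)
        self.loops = df

    def __len__(self):
        return len(self.loops)

    @property
    def spans(self) -> pd.DataFrame:
        """Full loop spans [start1, end2)."""
        return pd.DataFrame({
            "chrom": self.loops["chrom"],
            "start": self.loops["start1"],
            "end": self.loops["end2"],
        })


def read_loops_bedpe(path: str | Path, cell_type: str = "") -> LoopSet:
    """Read and validate a BEDPE loop list; trans rows are dropped (logged)."""
    df = formats.read_bedpe(path)
    bad = df["end1"] <= df["start1"]
    bad |= df["end2"] <= df["start2"]
    if bad.any():
        lineno = int(np.where(bad)[0][0]) + 1
        raise ValueError(f"{path}: line {lineno}: anchor end <= start")
    cis = df["chrom1"] == df["chrom2"]
    n_trans = int((~cis).sum())
    if n_trans:
        warnings.warn(f"{path}: dropped {n_trans} inter-chromosomal loop(s)",
                      RuntimeWarning)
    df = df[cis].rename(columns={"chrom1": "chrom"}).drop(columns=["chrom2"])
    return LoopSet(df[LOOP_COLS + [c for c in df.columns if c not in LOOP_COLS]],
                   cell_type=cell_type)


def write_loops_bedpe(loops: LoopSet, path: str | Path) -> None:
    df = loops.loops.copy()
    df["chrom1"] = df["chrom"]
    df["chrom2"] = df["chrom"]
    if "name" not in df:
        df["name"] = [f"loop_{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0
    formats.write_bedpe(df, path)


# ---------------------------------------------------------------------------
# APA
# ---------------------------------------------------------------------------

@dataclass
class ApaResult:
    aggregate: np.ndarray  # (2w+1, 2w+1) mean O/E submatrix
    score: float           # center / mean lower-left corner block
    n_loops_used: int
    n_loops_skipped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.aggregate)


def apa_score(
    cmap: ContactMap,
    loops: LoopSet,
    *,
    flank_bins: int = 10,
    min_separation: int | None = None,
) -> ApaResult:
    """Aggregate peak analysis over an O/E contact map.

    For each loop, the O/E submatrix centered on (anchor1 bin, anchor2 bin)
    ± ``flank_bins`` is extracted; submatrices are averaged across loops and
    the score is the center pixel divided by the mean of the lower-left
    (flank_bins/2)² corner block. Loops with anchor separation below
    ``min_separation`` (default 2 × flank window) or extending past the
    chromosome are skipped.
    """
    if cmap.state != "observed_over_expected":
        raise MatrixStateError("apa_score expects an observed/expected map")
    g = cmap.genome
    bs = g.bin_size
    w = flank_bins
    if min_separation is None:
        min_separation = 2 * w * bs
    agg = np.zeros((2 * w + 1, 2 * w + 1))
    used = skipped = 0
    for _, lp in loops.loops.iterrows():
        c = lp["chrom"]
        if c not in g.lengths:
            skipped += 1
            continue
        n = g.n_bins(c)
        a1 = int((lp["start1"] + lp["end1"]) // 2 // bs)
        a2 = int((lp["start2"] + lp["end2"]) // 2 // bs)
        if (a2 - a1) * bs < min_separation:
            skipped += 1
            continue
        if a1 - w < 0 or a2 + w >= n:
            skipped += 1
            continue
        agg += cmap.values[c][a1 - w: a1 + w + 1, a2 - w: a2 + w + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA")
    agg /= used
    cw = max(w // 2, 1)
    corner = agg[-cw:, :cw]  # lower-left: anchor1 side high, anchor2 side low
    denom = corner.mean()
    score = float(agg[w, w] / denom) if denom > 0 else np.inf
    return ApaResult(aggregate=agg, score=score,
                     n_loops_used=used, n_loops_skipped=skipped)


# ---------------------------------------------------------------------------
# Genes in loops
# ---------------------------------------------------------------------------

def genes_in_loops(genes: pd.DataFrame, loops: LoopSet,
                   mode: str = "span") -> pd.Series:
    """Boolean per-gene membership in the loop set.

    ``span`` mode: the gene overlaps [start1, end2) of any loop;
    ``anchors`` mode: the gene overlaps an anchor interval.
    """
    if mode not in ("span", "anchors"):
        raise ValueError("mode must be 'span' or 'anchors'")
    member = pd.Series(False, index=pd.Index(genes["name"], name="gene"))
    lp = loops.loops
    for _, g in genes.iterrows():
        sub = lp[lp["chrom"] == g["chrom"]]
        if mode == "span":
            hit = ((g["start"] < sub["end2"]) & (sub["start1"] < g["end"])).any()
        else:
            hit = (((g["start"] < sub["end1"]) & (sub["start1"] < g["end"]))
                   | ((g["start"] < sub["end2"]) & (sub["start2"] < g["end"]))).any()
        member[g["name"]] = bool(hit)
    return member


# ---------------------------------------------------------------------------
# CAL identification and the aCAL split
# ---------------------------------------------------------------------------

@dataclass
class CalSet:
    """Loops flagged as compartment-associating, with class annotations."""

    loops: pd.DataFrame  # LOOP_COLS + is_cal, interval_id, label (+ class later)
    intervals: pd.DataFrame  # compartment intervals used
    gene_sets: dict[str, pd.Index] = field(default_factory=dict)

    @property
    def cals(self) -> pd.DataFrame:
        return self.loops[self.loops["is_cal"]]

    def subset(self, cls: str) -> pd.DataFrame:
        sub = self.cals
        return sub[sub.get("compartment_class", pd.Series(index=sub.index)) == cls]


def identify_cals(loops: LoopSet, track: CompartmentTrack) -> CalSet:
    """Flag loops whose two anchors fall in one contiguous compartment interval.

    Anchor position is its midpoint, mapped to a compartment-resolution bin.
    Loops with an anchor in a masked bin are excluded (is_cal = NA dropped,
    count in ``attrs['n_masked']``).
    """
    ivs = compartment_intervals(track)
    g = track.genome
    bs = g.bin_size
    df = loops.loops.copy().reset_index(drop=True)
    iv_id = np.full(len(df), -1)
    labels = np.full(len(df), "", dtype="U1")
    masked = np.zeros(len(df), dtype=bool)
    # per-chromosome bin → interval id lookup
    lookup = {}
    for c in g.chrom_names:
        arr = np.full(g.n_bins(c), -1)
        for _, iv in ivs[ivs["chrom"] == c].iterrows():
            arr[iv["bin_start"]: iv["bin_end"]] = iv["interval_id"]
        lookup[c] = arr
    for k, lp in df.iterrows():
        c = lp["chrom"]
        if c not in lookup:
            masked[k] = True
            continue
        b1 = min(int((lp["start1"] + lp["end1"]) // 2 // bs), g.n_bins(c) - 1)
        b2 = min(int((lp["start2"] + lp["end2"]) // 2 // bs), g.n_bins(c) - 1)
        # an anchor in a masked bin is uninterpretable even when the masked
        # bin was bridged into an interval span
        if track.label[c][b1] not in ("A", "B") or \
                track.label[c][b2] not in ("A", "B"):
            masked[k] = True
            continue
        i1, i2 = lookup[c][b1], lookup[c][b2]
        if i1 < 0 or i2 < 0:
            masked[k] = True
            continue
        if i1 == i2:
            iv_id[k] = i1
            labels[k] = ivs.loc[ivs["interval_id"] == i1, "label"].iloc[0]
    if masked.any():
        warnings.warn(f"{masked.sum()} loop(s) with anchors in masked bins excluded",
                      RuntimeWarning)
    df["is_cal"] = iv_id >= 0
    df["interval_id"] = iv_id
    df["label"] = labels
    df = df[~masked].reset_index(drop=True)
    out = CalSet(loops=df, intervals=ivs)
    out.loops.attrs["n_masked"] = int(masked.sum())
    return out


def split_cals_by_class(
    cals: CalSet,
    classes: pd.DataFrame,
    genes: pd.DataFrame,
    *,
    mode: str = "span",
) -> CalSet:
    """Split CALs into aCALs / repressed CALs and form disjoint gene sets.

    ``classes`` is the output of ``cluster_compartment_classes`` indexed by
    (chrom, bin) with a ``compartment_class`` column; an interval's class is
    the majority class of its classified bins. CALs in intervals with no
    classified bin are dropped with a warning. Gene sets: genes overlapping
    aCAL spans (``in_aCALs``), repressed-CAL spans (``in_repressed_CALs``),
    all others (``out_of_CALs``); a gene overlapping both subsets goes to
    the side with the larger total overlap, ties to aCALs.
    """
    ivs = cals.intervals
    cls_by_bin = {(c, b): k for (c, b), k in
                  zip(zip(classes["chrom"], classes["bin"]),
                      classes["compartment_class"])}
    iv_class = {}
    for _, iv in ivs.iterrows():
        votes = [cls_by_bin.get((iv["chrom"], b))
                 for b in range(iv["bin_start"], iv["bin_end"])]
        votes = [v for v in votes if v is not None]
        if not votes:
            iv_class[iv["interval_id"]] = None
        else:
            act = votes.count(ACTIVATION)
            rep = votes.count(REPRESSION)
            iv_class[iv["interval_id"]] = ACTIVATION if act >= rep else REPRESSION

    df = cals.loops.copy()
    df["compartment_class"] = [
        iv_class.get(i) if i >= 0 else None for i in df["interval_id"]]
    n_drop = int((df["is_cal"] & df["compartment_class"].isna()).sum())
    if n_drop:
        warnings.warn(f"{n_drop} CAL(s) in unclassified intervals dropped",
                      RuntimeWarning)
        df = df[~(df["is_cal"] & df["compartment_class"].isna())]
    out = CalSet(loops=df.reset_index(drop=True), intervals=ivs)

    acal = LoopSet(df[df["is_cal"] & (df["compartment_class"] == ACTIVATION)][LOOP_COLS]) \
        if (df["is_cal"] & (df["compartment_class"] == ACTIVATION)).any() else None
    rcal = LoopSet(df[df["is_cal"] & (df["compartment_class"] == REPRESSION)][LOOP_COLS]) \
        if (df["is_cal"] & (df["compartment_class"] == REPRESSION)).any() else None
    in_a = genes_in_loops(genes, acal, mode) if acal is not None else \
        pd.Series(False, index=pd.Index(genes["name"], name="gene"))
    in_r = genes_in_loops(genes, rcal, mode) if rcal is not None else \
        pd.Series(False, index=pd.Index(genes["name"], name="gene"))
    both = in_a & in_r
    if both.any():
        # assign by larger total overlap with each subset's spans; ties → aCAL
        for name in both[both].index:
            g = genes.loc[genes["name"] == name].iloc[0]
            ov_a = _total_overlap(g, acal)
            ov_r = _total_overlap(g, rcal)
            if ov_r > ov_a:
                in_a[name] = False
            else:
                in_r[name] = False
    out.gene_sets = {
        "in_aCALs": in_a[in_a].index,
        "in_repressed_CALs": in_r[in_r].index,
        "out_of_CALs": in_a[~in_a & ~in_r].index,
    }
    return out


def _total_overlap(gene, loops: LoopSet) -> int:
    sub = loops.loops[loops.loops["chrom"] == gene["chrom"]]
    lo = np.maximum(sub["start1"].to_numpy(), gene["start"])
    hi = np.minimum(sub["end2"].to_numpy(), gene["end"])
    return int(np.maximum(hi - lo, 0).sum())


# ---------------------------------------------------------------------------
# Peak overlap test
# ---------------------------------------------------------------------------

def peak_overlap_test(
    regions: pd.DataFrame,
    peaks: pd.DataFrame,
    genome: BinnedGenome,
    *,
    n_shuffles: int = 1,
    seed: int = 0,
    mask: dict[str, np.ndarray] | None = None,
) -> dict:
    """Fisher's exact test of region–peak overlap against shuffled controls.

    ``regions`` (chrom,start,end — e.g. aCAL loop spans) are compared with
    length-matched regions placed uniformly at random on the same chromosome
    (``n_shuffles`` controls per region, seeded, avoiding masked bins). The
    2×2 table is (real vs control) × (overlaps ≥1 peak vs none), tested
    two-sided. Returns overlap fraction, odds ratio and p value.
    """
    if len(regions) == 0 or len(peaks) == 0:
        raise ValueError("empty regions or peaks")
    rng = np.random.default_rng(seed)

    peak_by_chrom = {c: sub[["start", "end"]].to_numpy()
                     for c, sub in peaks.groupby("chrom")}

    def hits(chrom, start, end) -> bool:
        arr = peak_by_chrom.get(chrom)
        if arr is None:
            return False
        return bool(((start < arr[:, 1]) & (arr[:, 0] < end)).any())

    def ok_placement(chrom, start, end) -> bool:
        if mask is None:
            return True
        bs = genome.bin_size
        m = mask.get(chrom)
        if m is None:
            return True
        return not m[start // bs: -(-end // bs)].any()

    real_hit = 0
    ctrl_hit = 0
    n_ctrl = 0
    for _, r in regions.iterrows():
        c, s, e = r["chrom"], int(r["start"]), int(r["end"])
        real_hit += hits(c, s, e)
        L = e - s
        limit = genome.lengths[c] - L
        if limit <= 0:
            continue
        for _ in range(n_shuffles):
            for _attempt in range(50):
                s2 = int(rng.integers(0, limit + 1))
                if ok_placement(c, s2, s2 + L):
                    break
            ctrl_hit += hits(c, s2, s2 + L)
            n_ctrl += 1
    n_real = len(regions)
    table = [[real_hit, n_real - real_hit], [ctrl_hit, n_ctrl - ctrl_hit]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "overlap_fraction": real_hit / n_real,
        "control_fraction": ctrl_hit / n_ctrl if n_ctrl else np.nan,
        "odds_ratio": float(odds),
        "p_value": float(p),
        "table": table,
    }
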