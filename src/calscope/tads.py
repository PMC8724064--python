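"""TAD calling via the directionality index + HMM, insulation scores, and
cross-cell-type TAD classification.

The directionality index (DI) contrasts a bin's upstream and downstream
contact sums within a window (2 Mb by convention): with A = sum of contacts
to upstream bins, B = sum to downstream bins, and E = (A+B)/2,

    DI = sign(B - A) * ((A-E)^2/E + (B-E)^2/E),

so DI is strongly positive at domain starts (downstream bias) and strongly
negative at domain ends. A 3-state Gaussian HMM segments the DI track; a TAD
runs from the start of a downstream-biased state run to the end of the next
upstream-biased run. Gaps between consecutive TADs shorter than 400 kb are
boundaries; longer gaps are unorganized regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .contacts import ContactMap, MatrixStateError
from .genome import BinnedGenome

__all__ = [
    "DITrack",
    "TadSet",
    "InsulationTrack",
    "directionality_index",
    "hmm_segment",
    "tads_from_states",
    "call_tads",
    "insulation_score",
    "tad_metaprofile",
    "classify_tads",
    "tad_genome_coverage",
]

MAX_BOUNDARY_BP = 400_000

STATE_DOWN = "downstream_bias"
STATE_NONE = "none"
STATE_UP = "upstream_bias"


@dataclass
class DITrack:
    genome: BinnedGenome
    di: dict[str, np.ndarray]
    window: int  # bp

    def flat(self) -> np.ndarray:
        return np.concatenate([self.di[c] for c in self.genome.chrom_names])

    def to_frame(self) -> pd.DataFrame:
        df = self.genome.bins()
        df["di"] = self.flat()
        return df


@dataclass
class InsulationTrack:
    genome: BinnedGenome
    score: dict[str, np.ndarray]  # log2 ratio to chromosome mean; NaN at ends
    window: int

    def to_frame(self) -> pd.DataFrame:
        df = self.genome.bins()
        df["insulation"] = np.concatenate(
            [self.score[c] for c in self.genome.chrom_names])
        return df


@dataclass
class TadSet:
    """Sorted, non-overlapping TAD intervals with boundary bookkeeping."""

    intervals: pd.DataFrame  # chrom, start, end (bp)
    boundaries: pd.DataFrame = field(default=None)  # gaps < 400 kb between TADs
    unorganized: pd.DataFrame = field(default=None)  # gaps >= 400 kb
    cell_type: str = ""

    def __post_init__(self):
        cols = ["chrom", "start", "end"]
        iv = self.intervals
        if len(iv):
            iv = iv.sort_values(cols[:2]).reset_index(drop=True)
            for c, sub in iv.groupby("chrom"):
                if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                    raise ValueError(f"overlapping TADs on {c}")
        self.intervals = iv
        if self.boundaries is None:
            self.boundaries = pd.DataFrame(columns=cols)
        if self.unorganized is None:
            self.unorganized = pd.DataFrame(columns=cols)

    def __len__(self):
        return len(self.intervals)


def directionality_index(cmap: ContactMap, window: int = 2_000_000) -> DITrack:
    """Dixon-style directionality index per bin.

    At chromosome ends the up/downstream sums use the available span
    (truncated window, no padding).
    """
    if cmap.state not in ("balanced", "raw"):
        raise MatrixStateError("directionality_index expects balanced (or raw) counts")
    g = cmap.genome
    w = window // g.bin_size
    if w < 2:
        raise ValueError("window must cover at least 2 bins")
    out = {}
    for c in g.chrom_names:
        v = cmap.values[c]
        n = v.shape[0]
        di = np.zeros(n)
        for i in range(n):
            a = v[i, max(i - w, 0): i].sum()
            b = v[i, i + 1: min(i + w + 1, n)].sum()
            e = (a + b) / 2.0
            if e == 0 or a == b:
                di[i] = 0.0
            else:
                di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
        mask = cmap.mask[c]
        di[mask] = 0.0
        out[c] = di
    return DITrack(genome=g, di=out, window=window)


def hmm_segment(
    di: DITrack,
    *,
    n_states: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    n_iter: int = 100,
) -> dict[str, np.ndarray]:
    """3-state Gaussian HMM over the DI track, decoded by Viterbi.

    Fitted genome-wide (all chromosomes as one multi-sequence sample) with
    seeded EM restarts; the best log-likelihood fit is kept. States are
    identified by emission mean: most positive → downstream_bias, most
    negative → upstream_bias, middle → none.
    """
    g = di.genome
    seqs = [di.di[c].reshape(-1, 1) for c in g.chrom_names]
    X = np.concatenate(seqs)
    lengths = [len(s) for s in seqs]
    if len(X) < 50:
        raise ValueError("fewer than 50 bins: too short to fit the HMM")
    if np.allclose(X, X[0]):
        # degenerate flat track: everything is the 'none' state
        return {c: np.full(len(di.di[c]), STATE_NONE, dtype="U15")
                for c in g.chrom_names}
    best = None
    best_ll = -np.inf
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_restarts):
        rs = int(child.generate_state(1)[0] % (2**31))
        model = GaussianHMM(n_components=n_states, covariance_type="diag",
                            n_iter=n_iter, random_state=rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X, lengths)
                ll = model.score(X, lengths)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if ll > best_ll:
            best_ll, best = ll, model
    if best is None:
        raise RuntimeError("HMM fitting failed in every restart")
    if not best.monitor_.converged:
        warnings.warn("HMM EM did not converge; best attempt used", RuntimeWarning)
    means = best.means_.ravel()
    name = np.full(n_states, STATE_NONE, dtype="U15")
    name[np.argmax(means)] = STATE_DOWN
    name[np.argmin(means)] = STATE_UP
    decoded = best.predict(X, lengths)
    out = {}
    pos = 0
    for c, ln in zip(g.chrom_names, lengths):
        out[c] = name[decoded[pos: pos + ln]]
        pos += ln
    return out


def _runs(states: np.ndarray):
    """Consecutive (state, start, end_exclusive) runs."""
    runs = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j + 1 < n and states[j + 1] == states[i]:
            j += 1
        runs.append((states[i], i, j + 1))
        i = j + 1
    return runs


def tads_from_states(
    states: dict[str, np.ndarray],
    genome: BinnedGenome,
    *,
    min_bins: int = 3,
    max_boundary_bp: int = MAX_BOUNDARY_BP,
    cell_type: str = "",
) -> TadSet:
    """Turn decoded HMM states into TAD intervals.

    A TAD opens at the start of a downstream-biased run and closes at the
    end of the last upstream-biased run before the next downstream run.
    Gaps between consecutive TADs shorter than ``max_boundary_bp`` are
    recorded as boundaries, longer gaps as unorganized regions.
    """
    bs = genome.bin_size
    tad_rows, bound_rows, unorg_rows = [], [], []
    for c in genome.chrom_names:
        st = states.get(c)
        if st is None or len(st) == 0:
            continue
        open_start = None
        last_up_end = None
        chrom_tads = []
        for name, b0, b1 in _runs(np.asarray(st)):
            if name == STATE_DOWN:
                if open_start is not None and last_up_end is not None:
                    chrom_tads.append((open_start, last_up_end))
                    open_start, last_up_end = b0, None
                elif open_start is None:
                    open_start = b0
                # a second downstream run without any upstream run in
                # between extends the search, keeping the original start
            elif name == STATE_UP and open_start is not None:
                last_up_end = b1
        if open_start is not None and last_up_end is not None:
            chrom_tads.append((open_start, last_up_end))
        chrom_tads = [(a, b) for a, b in chrom_tads if b - a >= min_bins]
        L = genome.lengths[c]
        for a, b in chrom_tads:
            tad_rows.append({"chrom": c, "start": a * bs, "end": min(b * bs, L)})
        for (a1, b1_), (a2, _) in zip(chrom_tads, chrom_tads[1:]):
            gap = (a2 - b1_) * bs
            row = {"chrom": c, "start": min(b1_ * bs, L), "end": min(a2 * bs, L)}
            if gap < max_boundary_bp:
                bound_rows.append(row)
            else:
                unorg_rows.append(row)
    cols = ["chrom", "start", "end"]
    return TadSet(
        intervals=pd.DataFrame(tad_rows, columns=cols),
        boundaries=pd.DataFrame(bound_rows, columns=cols),
        unorganized=pd.DataFrame(unorg_rows, columns=cols),
        cell_type=cell_type,
    )


def call_tads(cmap: ContactMap, *, window: int = 2_000_000, seed: int = 0,
              n_restarts: int = 10, cell_type: str = "") -> tuple[TadSet, DITrack]:
    """DI → HMM → TADs in one call."""
    di = directionality_index(cmap, window=window)
    states = hmm_segment(di, seed=seed, n_restarts=n_restarts)
    return tads_from_states(states, cmap.genome, cell_type=cell_type), di


# ---------------------------------------------------------------------------
# Insulation
# ---------------------------------------------------------------------------

def insulation_score(cmap: ContactMap, window: int = 500_000) -> InsulationTrack:
    """Mean contact intensity crossing each bin in a sliding square window.

    Raw IS(i) = mean of the (i-w..i-1) × (i+1..i+w) block; the reported
    score is log2(raw / chromosome mean of raw). Bins within ``w`` of a
    chromosome end are NaN.
    """
    if cmap.state not in ("balanced", "raw"):
        raise MatrixStateError("insulation_score expects balanced (or raw) counts")
    g = cmap.genome
    w = window // g.bin_size
    if w < 1:
        raise ValueError("window smaller than one bin")
    out = {}
    for c in g.chrom_names:
        v = cmap.values[c]
        n = v.shape[0]
        if 2 * w + 1 > n:
            raise ValueError(f"window exceeds chromosome {c}")
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            raw[i] = v[i - w: i, i + 1: i + w + 1].mean()
        ok = np.isfinite(raw) & (raw > 0)
        mean_raw = raw[np.isfinite(raw)].mean()
        score = np.full(n, np.nan)
        if mean_raw > 0:
            score[ok] = np.log2(raw[ok] / mean_raw)
        out[c] = score
    return InsulationTrack(genome=g, score=out, window=window)


def tad_metaprofile(is_track: InsulationTrack, tads: TadSet,
                    n_points: int = 100) -> np.ndarray:
    """Average insulation profile over TADs rescaled to unit length.

    Each TAD plus flanks of half its length is linearly interpolated onto
    ``n_points`` spanning [-0.5 TAD, +1.5 TAD] and profiles are averaged
    (NaN-aware). TADs shorter than 2 bins are skipped.
    """
    g = is_track.genome
    bs = g.bin_size
    profiles = []
    skipped = 0
    grid = np.linspace(-0.5, 1.5, n_points)
    for _, tad in tads.intervals.iterrows():
        c = tad["chrom"]
        L = tad["end"] - tad["start"]
        if L < 2 * bs:
            skipped += 1
            continue
        n = g.n_bins(c)
        centers = (np.arange(n) + 0.5) * bs
        # position of each grid point in bp
        pos = tad["start"] + grid * L
        vals = np.interp(pos, centers, is_track.score[c])
        # np.interp propagates NaN only at sampled NaNs; mask out-of-range
        vals = np.where((pos < centers[0]) | (pos > centers[-1]), np.nan, vals)
        profiles.append(vals)
    if skipped:
        warnings.warn(f"{skipped} TAD(s) shorter than 2 bins skipped", RuntimeWarning)
    if not profiles:
        return np.full(n_points, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.vstack(profiles), axis=0)


# ---------------------------------------------------------------------------
# Five-type TAD classification
# ---------------------------------------------------------------------------

def _overlap(s1, e1, s2, e2) -> int:
    return max(0, min(e1, e2) - max(s1, s2))


def classify_tads(
    reference: TadSet,
    other: TadSet,
    *,
    stable_threshold: float = 0.70,
    min_piece: float = 0.5,
    reciprocal: bool = True,
) -> pd.DataFrame:
    """Classify each reference TAD as stable / merged / split / reorganized /
    unique against another cell type's TAD set.

    Precedence (structurally decisive cases first):
      unique      — no other-set TAD overlaps the reference TAD R;
      split       — >= 2 other-set TADs each lie >= ``min_piece`` of their
                    own length inside R;
      merged      — one other-set TAD covers >= ``min_piece`` of R *and* of
                    at least one sibling reference TAD;
      stable      — best overlap > ``stable_threshold`` (reciprocal
                    intersection/union by default; one-sided optional);
      reorganized — everything else.
    """
    ref = reference.intervals
    oth = other.intervals
    rows = []
    for ri, R in ref.iterrows():
        cand = oth[(oth["chrom"] == R["chrom"]) & (oth["start"] < R["end"])
                   & (R["start"] < oth["end"])]
        if len(cand) == 0:
            rows.append({"chrom": R["chrom"], "start": R["start"], "end": R["end"],
                         "type": "unique", "best_overlap": 0.0})
            continue
        lenR = R["end"] - R["start"]
        ovl = np.array([_overlap(R["start"], R["end"], o["start"], o["end"])
                        for _, o in cand.iterrows()], dtype=float)
        len_o = (cand["end"] - cand["start"]).to_numpy(dtype=float)
        if reciprocal:
            frac = ovl / (lenR + len_o - ovl)  # intersection / union
        else:
            frac = ovl / lenR
        best = float(frac.max())
        # split: >= 2 other TADs mostly inside R
        inside = ovl / len_o >= min_piece
        if inside.sum() >= 2:
            rows.append({"chrom": R["chrom"], "start": R["start"], "end": R["end"],
                         "type": "split", "best_overlap": best})
            continue
        # merged: one other TAD covers >= min_piece of R and of a sibling
        merged = False
        for (_, o), cov_R in zip(cand.iterrows(), ovl / lenR):
            if cov_R < min_piece:
                continue
            sib = ref[(ref.index != ri) & (ref["chrom"] == R["chrom"])
                      & (ref["start"] < o["end"]) & (o["start"] < ref["end"])]
            for _, S in sib.iterrows():
                lenS = S["end"] - S["start"]
                if _overlap(S["start"], S["end"], o["start"], o["end"]) / lenS >= min_piece:
                    merged = True
                    break
            if merged:
                break
        if merged:
            rows.append({"chrom": R["chrom"], "start": R["start"], "end": R["end"],
                         "type": "merged", "best_overlap": best})
            continue
        typ = "stable" if best > stable_threshold else "reorganized"
        rows.append({"chrom": R["chrom"], "start": R["start"], "end": R["end"],
                     "type": typ, "best_overlap": best})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "best_overlap"])


def tad_genome_coverage(tads: TadSet, genome: BinnedGenome) -> float:
    """Fraction of the genome covered by TADs."""
    total = sum(genome.chrom_lengths)
    cov = float((tads.intervals["end"] - tads.intervals["start"]).sum()) if len(tads) else 0.0
    return cov / total
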