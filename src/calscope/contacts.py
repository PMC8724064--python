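"""Contact-matrix data model and core Hi-C matrix transforms.

A :class:`ContactMap` holds one symmetric intra-chromosomal matrix per
chromosome (dense, since the package targets per-chromosome analysis at
compartment/TAD resolutions), a per-bin exclusion mask, and a ``state`` tag
tracking which transform chain produced it:

``raw`` → :func:`ice_normalize` → ``balanced`` →
:func:`observed_over_expected` → ``observed_over_expected`` →
:func:`correlation_matrix` → ``correlation``.

On-disk format is HiC-Pro style sparse triplet text (``bin_i  bin_j  count``,
1-based global bin indices, upper triangle) with a companion BED bin table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedGenome

__all__ = [
    "ContactMap",
    "PsCurve",
    "read_contact_map",
    "write_contact_map",
    "ice_normalize",
    "observed_over_expected",
    "correlation_matrix",
    "contact_probability",
    "replicate_correlation",
    "cis_short_fraction",
]

STATES = ("raw", "balanced", "observed_over_expected", "correlation")


class MatrixStateError(ValueError):
    """Operation applied to a ContactMap in the wrong state."""


class MatrixIntegrityError(ValueError):
    """Input file violates the contact-matrix contract."""


@dataclass
class ContactMap:
    """Per-chromosome symmetric contact matrices on a binned genome.

    Attributes
    ----------
    genome
        The binning the matrices live on.
    values
        chrom → (n_bins × n_bins) symmetric non-negative array.
    mask
        chrom → boolean array, True for bins excluded from analysis.
        Masked bins have all-zero rows/columns.
    state
        One of ``raw``, ``balanced``, ``observed_over_expected``,
        ``correlation``.
    metadata
        Free-form provenance (ICE scale factor, convergence flag, ...).
    """

    genome: BinnedGenome
    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    state: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        for c in self.genome.chrom_names:
            if c not in self.values:
                raise ValueError(f"missing matrix for chromosome {c}")
            n = self.genome.n_bins(c)
            if self.values[c].shape != (n, n):
                raise ValueError(f"matrix shape mismatch on {c}")
            if c not in self.mask:
                self.mask[c] = np.zeros(n, dtype=bool)

    @classmethod
    def zeros(cls, genome: BinnedGenome, state: str = "raw") -> "ContactMap":
        vals = {c: np.zeros((genome.n_bins(c),) * 2) for c in genome.chrom_names}
        msk = {c: np.zeros(genome.n_bins(c), dtype=bool) for c in genome.chrom_names}
        return cls(genome, vals, msk, state)

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.genome,
            {c: v.copy() for c, v in self.values.items()},
            {c: m.copy() for c, m in self.mask.items()},
            self.state,
            dict(self.metadata),
        )

    def apply_mask(self) -> None:
        """Zero out rows/columns of masked bins, in place."""
        for c in self.genome.chrom_names:
            m = self.mask[c]
            if m.any():
                self.values[c][m, :] = 0.0
                self.values[c][:, m] = 0.0

    def check_symmetry(self, tol: float = 1e-8) -> bool:
        return all(
            np.allclose(v, v.T, atol=tol, rtol=0) for v in self.values.values()
        )

    def total_contacts(self) -> float:
        """Sum over unique intra-chromosomal pairs (diagonal counted once)."""
        tot = 0.0
        for v in self.values.values():
            tot += np.triu(v).sum()
        return float(tot)

    def coarsen(self, factor: int) -> "ContactMap":
        """Sum counts into ``factor``-times-larger bins (raw state only)."""
        if self.state != "raw":
            raise MatrixStateError("coarsen operates on raw counts")
        coarse = self.genome.coarsen(factor)
        vals, msk = {}, {}
        for c in self.genome.chrom_names:
            n = self.genome.n_bins(c)
            m = coarse.n_bins(c)
            idx = np.arange(n) // factor
            agg = np.zeros((m, m))
            np.add.at(agg, (idx[:, None], idx[None, :]), self.values[c])
            vals[c] = agg
            msk[c] = np.zeros(m, dtype=bool)
        return ContactMap(coarse, vals, msk, "raw", dict(self.metadata))

    def __add__(self, other: "ContactMap") -> "ContactMap":
        """Merge raw replicates by count summation."""
        if self.genome != other.genome:
            raise ValueError("cannot merge maps on different genomes")
        if self.state != "raw" or other.state != "raw":
            raise MatrixStateError("replicate merging operates on raw counts")
        out = self.copy()
        for c in out.genome.chrom_names:
            out.values[c] = out.values[c] + other.values[c]
        return out


@dataclass
class PsCurve:
    """Contact probability as a function of genomic separation.

    ``probabilities`` sum to 1 over the reported separations.
    """

    distances: np.ndarray  # bp, strictly increasing multiples of bin_size
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance_bp": self.distances, "probability": self.probabilities}
        )

    def loglog_slope(self) -> float:
        """Least-squares slope of log10 p(s) vs log10 s (positive p only)."""
        ok = self.probabilities > 0
        x = np.log10(self.distances[ok])
        y = np.log10(self.probabilities[ok])
        return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# I/O: HiC-Pro triplet + BED bin table
# ---------------------------------------------------------------------------

def write_bins_bed(genome: BinnedGenome, path: str | Path) -> None:
    bins = genome.bins()
    bins["index"] = np.arange(1, len(bins) + 1)  # HiC-Pro uses 1-based indices
    bins.to_csv(path, sep="\t", header=False, index=False)


def read_bins_bed(path: str | Path) -> BinnedGenome:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "index"],
        dtype={"chrom": str},
    )
    names, lengths = [], []
    for c, sub in df.groupby("chrom", sort=False):
        names.append(c)
        lengths.append(int(sub["end"].max()))
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(widths.max())
    return BinnedGenome(tuple(names), tuple(lengths), bin_size)


def write_contact_map(cmap: ContactMap, matrix_path: str | Path,
                      bed_path: str | Path | None = None) -> None:
    """Write upper-triangle nonzero entries as 1-based global triplets."""
    if bed_path is not None:
        write_bins_bed(cmap.genome, bed_path)
    with open(matrix_path, "w") as fh:
        for c in cmap.genome.chrom_names:
            off = cmap.genome.chrom_offset(c)
            v = cmap.values[c]
            ii, jj = np.nonzero(np.triu(v))
            for i, j in zip(ii, jj):
                x = v[i, j]
                s = f"{x:.10g}" if cmap.state != "raw" else str(int(round(x)))
                fh.write(f"{off + i + 1}\t{off + j + 1}\t{s}\n")


def read_contact_map(
    matrix_path: str | Path,
    genome: BinnedGenome | None = None,
    *,
    bed_path: str | Path | None = None,
    format: str = "hicpro_triplet",
    bin_size: int | None = None,
) -> ContactMap:
    """Read a raw contact map from HiC-Pro triplet text.

    Either ``genome`` or ``bed_path`` (companion bin table) must be given.
    Entries are symmetrized; a pair reported twice with conflicting counts
    raises :class:`MatrixIntegrityError`.
    """
    if format != "hicpro_triplet":
        raise ValueError(f"unsupported format {format!r} (hicpro_triplet only)")
    if genome is None:
        if bed_path is None:
            raise ValueError("need a BinnedGenome or a companion BED bin table")
        genome = read_bins_bed(bed_path)
    if bin_size is not None and bin_size != genome.bin_size:
        raise ValueError(
            f"requested bin_size {bin_size} != file binning {genome.bin_size}"
        )
    cmap = ContactMap.zeros(genome)
    # global index → (chrom, local index)
    bounds, chroms = [], []
    off = 0
    for c in genome.chrom_names:
        bounds.append(off)
        chroms.append(c)
        off += genome.n_bins(c)
    total = off
    bounds = np.asarray(bounds + [total])

    seen: dict[tuple[int, int], float] = {}
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                gi, gj = int(parts[0]) - 1, int(parts[1]) - 1
                count = float(parts[2])
            except (ValueError, IndexError) as exc:
                raise MatrixIntegrityError(
                    f"{matrix_path}: malformed line {lineno}: {line!r}"
                ) from exc
            if not (0 <= gi < total and 0 <= gj < total):
                raise MatrixIntegrityError(
                    f"{matrix_path}: line {lineno}: bin index out of range"
                )
            if count < 0:
                raise MatrixIntegrityError(
                    f"{matrix_path}: line {lineno}: negative count"
                )
            key = (min(gi, gj), max(gi, gj))
            if key in seen and seen[key] != count:
                raise MatrixIntegrityError(
                    f"{matrix_path}: line {lineno}: conflicting duplicate for pair {key}"
                )
            seen[key] = count
            ci = int(np.searchsorted(bounds, gi, side="right") - 1)
            cj = int(np.searchsorted(bounds, gj, side="right") - 1)
            if ci != cj:
                # trans contacts kept only in the total-read accounting
                cmap.metadata["trans_total"] = cmap.metadata.get("trans_total", 0.0) + count
                continue
            c = chroms[ci]
            li, lj = gi - bounds[ci], gj - bounds[cj]
            cmap.values[c][li, lj] = count
            cmap.values[c][lj, li] = count
    return cmap


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_normalize(
    cmap: ContactMap,
    max_iter: int = 200,
    tol: float = 1e-5,
    low_coverage_quantile: float = 0.02,
) -> ContactMap:
    """Iterative correction (ICE) of a raw contact map.

    Bins whose marginal sum falls at or below ``low_coverage_quantile`` of
    the per-chromosome marginal distribution (or is zero) are masked before
    correction. Rows/columns are iteratively rescaled until every unmasked
    marginal differs from the mean marginal by less than ``tol`` (relative).
    The result is rescaled so the mean unmasked marginal equals 1; the
    discarded global scale is stored in ``metadata['ice_scale']``.
    """
    if cmap.state != "raw":
        raise MatrixStateError("ice_normalize expects a raw-state map")
    out = cmap.copy()
    out.state = "balanced"
    converged = True
    scales = {}
    for c in out.genome.chrom_names:
        w = out.values[c].astype(float)
        marg = w.sum(axis=1)
        mask = out.mask[c].copy()
        nz = marg[~mask & (marg > 0)]
        if nz.size:
            cutoff = np.quantile(nz, low_coverage_quantile)
            mask |= marg < cutoff
        mask |= marg == 0
        if mask.all():
            raise ValueError(f"all bins masked on chromosome {c}")
        w[mask, :] = 0.0
        w[:, mask] = 0.0
        ok = ~mask
        for _ in range(max_iter):
            s = w.sum(axis=1)
            mean_s = s[ok].mean()
            if mean_s == 0:
                raise ValueError(f"chromosome {c} has no contacts among unmasked bins")
            dev = np.abs(s[ok] / mean_s - 1.0).max()
            if dev < tol:
                break
            b = np.ones_like(s)
            b[ok] = s[ok] / mean_s
            w /= np.outer(b, b)
        else:
            converged = False
        s = w.sum(axis=1)
        scale = s[ok].mean()
        if scale > 0:
            w /= scale
        scales[c] = float(scale)
        out.values[c] = w
        out.mask[c] = mask
    out.metadata["ice_scale"] = scales
    out.metadata["ice_converged"] = converged
    if not converged:
        warnings.warn("ICE did not converge within max_iter", RuntimeWarning)
    return out


# ---------------------------------------------------------------------------
# Expected / correlation transforms
# ---------------------------------------------------------------------------

def expected_by_distance(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean unmasked entry at each separation d = 0..n-1 (NaN if none)."""
    n = values.shape[0]
    ok = ~mask
    exp = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(values, offset=d)
        keep = ok[: n - d] & ok[d:]
        if keep.any():
            exp[d] = diag[keep].mean()
    return exp


def observed_over_expected(cmap: ContactMap) -> ContactMap:
    """Divide each entry by the per-chromosome mean at its separation."""
    if cmap.state != "balanced":
        raise MatrixStateError("observed_over_expected expects a balanced map")
    out = cmap.copy()
    out.state = "observed_over_expected"
    for c in out.genome.chrom_names:
        v = out.values[c]
        n = v.shape[0]
        exp = expected_by_distance(v, out.mask[c])
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        e = exp[d]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where((e > 0) & np.isfinite(e), v / e, 0.0)
        out.values[c] = oe
    out.apply_mask()
    return out


def correlation_matrix(cmap: ContactMap) -> ContactMap:
    """Pearson correlation of unmasked O/E rows; constant rows get masked."""
    if cmap.state != "observed_over_expected":
        raise MatrixStateError("correlation_matrix expects an O/E map")
    out = cmap.copy()
    out.state = "correlation"
    for c in out.genome.chrom_names:
        v = out.values[c]
        mask = out.mask[c].copy()
        ok = np.where(~mask)[0]
        if ok.size == 0:
            out.values[c] = np.zeros_like(v)
            continue
        sub = v[np.ix_(ok, ok)]
        sd = sub.std(axis=1)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"{const.sum()} constant O/E row(s) auto-masked on {c}", RuntimeWarning
            )
            mask[ok[const]] = True
            ok = ok[~const]
            sub = v[np.ix_(ok, ok)]
        corr = np.zeros_like(v)
        if ok.size >= 2:
            cc = np.corrcoef(sub)
            np.fill_diagonal(cc, 1.0)
            corr[np.ix_(ok, ok)] = np.clip(cc, -1.0, 1.0)
        elif ok.size == 1:
            corr[ok[0], ok[0]] = 1.0
        out.values[c] = corr
        out.mask[c] = mask
    out.apply_mask()
    return out


# ---------------------------------------------------------------------------
# p(s), replicate QC, cis fractions
# ---------------------------------------------------------------------------

def contact_probability(cmap: ContactMap, bin_size: int | None = None) -> PsCurve:
    """Contact probability p(s) over intra-chromosomal separations.

    For each separation s (multiples of the bin size, s >= 1 bin) the
    interaction counts are summed across chromosomes and divided by the
    number of possible bin pairs at that separation; the curve is then
    renormalized to sum to 1.
    """
    if cmap.state not in ("raw", "balanced"):
        raise MatrixStateError("contact_probability expects raw or balanced counts")
    bs = bin_size or cmap.genome.bin_size
    if bs != cmap.genome.bin_size:
        raise ValueError("bin_size must match the map's binning")
    max_d = max(cmap.genome.n_bins(c) for c in cmap.genome.chrom_names) - 1
    if max_d < 1 or cmap.total_contacts() == 0:
        raise ValueError("empty contact map")
    sums = np.zeros(max_d + 1)
    pairs = np.zeros(max_d + 1)
    for c in cmap.genome.chrom_names:
        v = cmap.values[c]
        n = v.shape[0]
        for d in range(1, n):
            sums[d] += np.diagonal(v, offset=d).sum()
            pairs[d] += n - d
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(pairs > 0, sums / pairs, 0.0)
    p = p[1:]
    total = p.sum()
    if total == 0:
        raise ValueError("no off-diagonal contacts")
    p /= total
    dist = np.arange(1, max_d + 1) * bs
    return PsCurve(distances=dist, probabilities=p)


def replicate_correlation(rep1: ContactMap, rep2: ContactMap,
                          max_dist: int = 2_000_000) -> float:
    """Pearson correlation between two replicates over near-diagonal pairs.

    Uses all unmasked intra-chromosomal pairs (i, j), i <= j, with
    separation |i-j| * bin_size <= ``max_dist``.
    """
    if rep1.genome != rep2.genome:
        raise ValueError("replicates must share binning")
    g = rep1.genome
    wmax = max_dist // g.bin_size
    xs, ys = [], []
    for c in g.chrom_names:
        n = g.n_bins(c)
        ok = ~(rep1.mask[c] | rep2.mask[c])
        for d in range(0, min(wmax, n - 1) + 1):
            keep = ok[: n - d] & ok[d:]
            xs.append(np.diagonal(rep1.values[c], offset=d)[keep])
            ys.append(np.diagonal(rep2.values[c], offset=d)[keep])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 2:
        raise ValueError("too few pairs for correlation")
    return float(np.corrcoef(x, y)[0, 1])


def cis_short_fraction(cmap: ContactMap,
                       thresholds: list[int] = (20_000, 40_000, 80_000, 100_000, 120_000),
                       ) -> pd.DataFrame:
    """Fraction of cis contacts at separations below each threshold.

    Separation of pair (i, j) is |i-j| * bin_size; the denominator is the
    total intra-chromosomal count over unique off-diagonal pairs.
    """
    if cmap.state != "raw":
        raise MatrixStateError("cis_short_fraction expects raw counts")
    bs = cmap.genome.bin_size
    max_d = max(cmap.genome.n_bins(c) for c in cmap.genome.chrom_names) - 1
    per_d = np.zeros(max_d + 1)
    for c in cmap.genome.chrom_names:
        v = cmap.values[c]
        for d in range(1, v.shape[0]):
            per_d[d] += np.diagonal(v, offset=d).sum()
    total = per_d.sum()
    rows = []
    for t in thresholds:
        if t < bs:
            warnings.warn(f"threshold {t} below bin size; fraction reported as 0",
                          RuntimeWarning)
            frac = 0.0
        else:
            dmax = int(np.ceil(t / bs)) - 1  # separations strictly below t
            frac = per_d[1 : dmax + 1].sum() / total if total > 0 else 0.0
        rows.append({"threshold_bp": int(t), "fraction": float(frac)})
    return pd.DataFrame(rows)
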