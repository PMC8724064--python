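"""A/B compartment calling and downstream compartment statistics.

Compartments are read from the sign of the leading eigenvector (PC1) of the
per-chromosome Hi-C correlation matrix at compartment resolution (400 kb by
convention): positive PC1 = A (active), negative = B (inactive). Because an
eigenvector's sign is arbitrary, PC1 is oriented per chromosome so it
correlates positively with an activity covariate — gene density by default,
mean expression as a fallback — which anchors A to the gene-rich, highly
expressed state.

Also here: replicate-concordant compartment-switch detection, k-means
clustering of per-bin PC1 profiles into reference-cell activation/repression
classes, and the expression–PC1 concordance permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .contacts import ContactMap, MatrixStateError
from .genome import BinnedGenome

__all__ = [
    "CompartmentTrack",
    "compartment_intervals",
    "gene_density_track",
    "call_compartments",
    "detect_switches",
    "cluster_compartment_classes",
    "assign_gene_compartment",
    "gene_concordance_test",
]

ACTIVATION = "activation"
REPRESSION = "repression"


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values and A/B labels for one cell type / replicate."""

    genome: BinnedGenome
    pc1: dict[str, np.ndarray]
    label: dict[str, np.ndarray]  # 'A' / 'B' / 'masked'
    cell_type: str = ""
    replicate: str = "merged"

    def pc1_flat(self) -> np.ndarray:
        return np.concatenate([self.pc1[c] for c in self.genome.chrom_names])

    def label_flat(self) -> np.ndarray:
        return np.concatenate([self.label[c] for c in self.genome.chrom_names])

    def to_frame(self) -> pd.DataFrame:
        df = self.genome.bins()
        df["pc1"] = self.pc1_flat()
        df["label"] = self.label_flat()
        return df


def compartment_intervals(track: CompartmentTrack,
                          bridge_masked: int = 1) -> pd.DataFrame:
    """Contiguous same-label compartment intervals.

    A masked bin carries no label but is not evidence of a compartment
    boundary, so runs are bridged across up to ``bridge_masked`` consecutive
    masked bins when the labels on both sides agree; longer masked gaps (or
    label changes) end the interval. Returns chrom, start, end (bp), label,
    interval_id and bin ranges.
    """
    rows = []
    iid = 0
    g = track.genome
    for c in g.chrom_names:
        lab = track.label[c]
        n = len(lab)
        b = 0
        while b < n:
            if lab[b] not in ("A", "B"):
                b += 1
                continue
            b1 = b
            while b1 + 1 < n:
                if lab[b1 + 1] == lab[b]:
                    b1 += 1
                    continue
                # try to bridge a short masked gap
                j = b1 + 1
                while j < n and lab[j] not in ("A", "B") and j - b1 - 1 < bridge_masked:
                    j += 1
                if j < n and lab[j] == lab[b] and j > b1 + 1:
                    b1 = j
                    continue
                break
            rows.append({
                "chrom": c, "start": b * g.bin_size,
                "end": min((b1 + 1) * g.bin_size, g.lengths[c]),
                "label": lab[b], "interval_id": iid,
                "bin_start": b, "bin_end": b1 + 1,
            })
            iid += 1
            b = b1 + 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "interval_id",
                       "bin_start", "bin_end"])


def gene_density_track(genes: pd.DataFrame, genome: BinnedGenome) -> dict[str, np.ndarray]:
    """Gene TSS count per bin — the fallback PC1 orientation covariate."""
    out = {c: np.zeros(genome.n_bins(c)) for c in genome.chrom_names}
    for _, g in genes.iterrows():
        c = g["chrom"]
        if c not in out:
            continue
        tss = int(g["start"] if g.get("strand", "+") == "+" else g["end"] - 1)
        b = min(tss // genome.bin_size, genome.n_bins(c) - 1)
        out[c][b] += 1
    return out


def expression_orientation_track(
    genes: pd.DataFrame,
    fpkm: pd.Series,
    genome: BinnedGenome,
) -> dict[str, np.ndarray]:
    """Per-bin mean log2(FPKM+1) — the preferred PC1 orientation covariate.

    Expression is cell-type specific, so orienting each cell type's PC1 by
    its own expression stays valid even where compartments have switched
    wholesale relative to a static gene-density landscape.
    """
    sums = {c: np.zeros(genome.n_bins(c)) for c in genome.chrom_names}
    counts = {c: np.zeros(genome.n_bins(c)) for c in genome.chrom_names}
    fpkm = fpkm.groupby(level=0).mean() if fpkm.index.has_duplicates else fpkm
    for _, g in genes.iterrows():
        c = g["chrom"]
        if c not in sums or g["name"] not in fpkm.index:
            continue
        tss = int(g["start"] if g.get("strand", "+") == "+" else g["end"] - 1)
        b = min(tss // genome.bin_size, genome.n_bins(c) - 1)
        sums[c][b] += np.log2(float(fpkm[g["name"]]) + 1.0)
        counts[c][b] += 1
    return {c: np.divide(sums[c], counts[c], out=np.zeros_like(sums[c]),
                         where=counts[c] > 0)
            for c in genome.chrom_names}


def call_compartments(
    corr: ContactMap,
    orientation: dict[str, np.ndarray],
    *,
    cell_type: str = "",
    replicate: str = "merged",
    min_bins: int = 10,
) -> CompartmentTrack:
    """Leading eigenvector of the correlation matrix, sign-oriented.

    Per chromosome, PC1 is the eigenvector of the unmasked correlation
    submatrix with the largest eigenvalue, oriented so its correlation with
    the ``orientation`` covariate is positive; A ⇔ pc1 > 0, B ⇔ pc1 < 0.
    Chromosomes with fewer than ``min_bins`` unmasked bins are fully masked.
    """
    if corr.state != "correlation":
        raise MatrixStateError("call_compartments expects a correlation-state map")
    g = corr.genome
    pc1, label = {}, {}
    for c in g.chrom_names:
        n = g.n_bins(c)
        v = np.zeros(n)
        lab = np.full(n, "masked", dtype="U6")
        ok = np.where(~corr.mask[c])[0]
        if ok.size < min_bins:
            warnings.warn(f"{c}: only {ok.size} unmasked bins; compartments masked",
                          RuntimeWarning)
            pc1[c], label[c] = v, lab
            continue
        sub = corr.values[c][np.ix_(ok, ok)]
        w, vec = np.linalg.eigh(sub)
        e1 = vec[:, -1]  # eigenvalues ascending
        orient = np.asarray(orientation[c], dtype=float)[ok]
        if np.std(orient) > 0 and np.std(e1) > 0:
            r = np.corrcoef(e1, orient)[0, 1]
        else:
            r = 0.0
        if r < 0:
            e1 = -e1
        elif r == 0 and e1[np.argmax(np.abs(e1))] < 0:
            e1 = -e1  # deterministic fallback: largest-|component| positive
        v[ok] = e1
        lab[ok] = np.where(e1 > 0, "A", np.where(e1 < 0, "B", "masked"))
        pc1[c], label[c] = v, lab
    return CompartmentTrack(genome=g, pc1=pc1, label=label,
                            cell_type=cell_type, replicate=replicate)


# ---------------------------------------------------------------------------
# Compartment switches
# ---------------------------------------------------------------------------

def detect_switches(
    tracks: dict[str, list[CompartmentTrack]],
    reference_cell: str,
) -> pd.DataFrame:
    """Replicate-concordant compartment switches versus a reference cell.

    A bin switches A→B (B→A) against the reference iff *both* reference
    replicates have positive (negative) PC1 and *both* comparison replicates
    negative (positive). If either cell's replicate pair disagrees in sign,
    the bin is 'discordant'; same concordant sign in both cells is 'stable'.

    Returns rows (chrom, bin, cell_type_pair, direction).
    """
    if any(len(reps) != 2 for reps in tracks.values()):
        raise ValueError("detect_switches requires exactly two replicates per cell type")
    ref1, ref2 = tracks[reference_cell]
    g = ref1.genome
    rows = []
    for other, (cmp1, cmp2) in tracks.items():
        if other == reference_cell:
            continue
        for c in g.chrom_names:
            r1, r2 = np.sign(ref1.pc1[c]), np.sign(ref2.pc1[c])
            c1, c2 = np.sign(cmp1.pc1[c]), np.sign(cmp2.pc1[c])
            masked = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
            ref_conc = r1 == r2
            cmp_conc = c1 == c2
            direction = np.full(len(r1), "discordant", dtype="U10")
            both = ref_conc & cmp_conc
            direction[both & (r1 == c1)] = "stable"
            direction[both & (r1 > 0) & (c1 < 0)] = "A->B"
            direction[both & (r1 < 0) & (c1 > 0)] = "B->A"
            direction[masked] = "masked"
            for b in range(len(r1)):
                rows.append({"chrom": c, "bin": b,
                             "cell_type_pair": f"{reference_cell}|{other}",
                             "direction": direction[b]})
    return pd.DataFrame(rows)


def switching_bins(switches: pd.DataFrame) -> pd.DataFrame:
    """Bins that switch (either direction) in at least one comparison."""
    sw = switches[switches["direction"].isin(["A->B", "B->A"])]
    return sw[["chrom", "bin"]].drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------------------
# Compartment classes (k-means on PC1 profiles)
# ---------------------------------------------------------------------------

def cluster_compartment_classes(
    pc1_profiles: pd.DataFrame,
    reference_cell: str,
    *,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
) -> pd.DataFrame:
    """k-means (k=2) on per-bin PC1 profiles across cell types.

    ``pc1_profiles``: rows = bins (index carries chrom/bin), columns = cell
    types, values = PC1. The cluster with the higher mean reference-cell PC1
    is named 'activation', the other 'repression'. Features are raw PC1
    values (shared units across cell types, so no standardization).
    """
    if len(pc1_profiles) < k:
        raise ValueError(f"need at least {k} bins to form {k} clusters")
    X = pc1_profiles.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all PC1 profiles identical")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(X)
    ref_means = [
        pc1_profiles[reference_cell].to_numpy()[assign == j].mean() for j in range(k)
    ]
    order = np.argsort(ref_means)[::-1]  # highest reference PC1 first
    names = {int(order[0]): ACTIVATION}
    for j in order[1:]:
        names[int(j)] = REPRESSION
    out = pc1_profiles.copy()
    out["compartment_class"] = [names[a] for a in assign]
    out.attrs["centroids"] = km.cluster_centers_
    out.attrs["inertia"] = float(km.inertia_)
    return out


# ---------------------------------------------------------------------------
# Gene ↔ compartment assignment and the concordance test
# ---------------------------------------------------------------------------

def assign_gene_compartment(genes: pd.DataFrame, track: CompartmentTrack) -> pd.DataFrame:
    """Per-gene PC1 and label from the bin containing the gene's TSS."""
    rows = []
    g = track.genome
    for _, gene in genes.iterrows():
        c = gene["chrom"]
        if c not in g.lengths:
            raise ValueError(f"gene {gene['name']}: unknown chromosome {c}")
        tss = int(gene["start"] if gene.get("strand", "+") == "+" else gene["end"] - 1)
        if not (0 <= tss < g.lengths[c]):
            raise ValueError(f"gene {gene['name']}: TSS outside {c}")
        b = tss // g.bin_size
        rows.append({"name": gene["name"], "chrom": c, "bin": b,
                     "pc1": float(track.pc1[c][b]), "label": track.label[c][b]})
    return pd.DataFrame(rows).set_index("name")


def gene_concordance_test(
    expr: pd.DataFrame,
    tracks: dict[str, CompartmentTrack],
    *,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    two_sided: bool = False,
    log_fpkm: bool = False,
) -> pd.DataFrame:
    """Permutation test of expression–PC1 covariance across cell types.

    Per gene, the statistic is the covariance between its FPKM vector and
    its PC1 vector over the cell types. The null is built by randomly
    shuffling the FPKM vector ``n_perm`` times;
    ``p = (1 + #{null > observed}) / (n_perm + 1)`` (upper tail by default —
    concordance is same-direction co-variation — with strict exceedances;
    see the methods note on ties among the 120 distinct permutations of a
    length-5 vector). ``two_sided=True`` compares |covariance| instead.
    Concordant ⇔ p < alpha. Genes with a masked PC1 in any cell type are
    excluded (reason recorded in ``attrs['excluded']``).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    cell_types = [ct for ct in expr.columns if ct in tracks]
    if len(cell_types) < 3:
        raise ValueError("need PC1 tracks for at least 3 cell types")
    # per-gene PC1 matrix; gene coordinates travel in expr.attrs['genes']
    genes = expr.index
    pc1 = pd.DataFrame(index=genes, columns=cell_types, dtype=float)
    masked = pd.Series(False, index=genes)
    gene_table = expr.attrs.get("genes")
    if gene_table is None:
        raise ValueError("expr.attrs['genes'] must hold the gene table "
                         "(chrom/start/end/name/strand)")
    gt = gene_table[gene_table["name"].isin(set(genes))].drop_duplicates("name")
    for ct in cell_types:
        assigned = assign_gene_compartment(gt, tracks[ct])
        pc1[ct] = assigned["pc1"].reindex(genes)
        masked |= assigned["label"].reindex(genes).isin(["masked"]) | pc1[ct].isna()
    excluded = genes[masked]
    keep = genes[~masked]

    X = expr.loc[keep, cell_types].to_numpy(dtype=float)
    if log_fpkm:
        X = np.log2(X + 1.0)
    Y = pc1.loc[keep, cell_types].to_numpy(dtype=float)
    nct = len(cell_types)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    obs = (Xc * Yc).mean(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(keep), dtype=np.int64)
    cmp_obs = np.abs(obs) if two_sided else obs
    for _ in range(n_perm):
        # independent permutation per gene via random-key argsort
        idx = np.argsort(rng.random(X.shape), axis=1)
        Xp = np.take_along_axis(Xc, idx, axis=1)
        null = (Xp * Yc).mean(axis=1)
        cmp_null = np.abs(null) if two_sided else null
        exceed += cmp_null > cmp_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    # a constant FPKM or PC1 vector carries no ordering information: the
    # statistic is 0 by construction and permutation cannot rank it
    degenerate = (Xc.std(axis=1) == 0) | (Yc.std(axis=1) == 0)
    p[degenerate] = 1.0
    obs[degenerate] = 0.0
    out = pd.DataFrame({
        "covariance": obs, "p_value": p, "concordant": p < alpha,
    }, index=keep)
    out.attrs["excluded"] = list(excluded)
    out.attrs["n_perm"] = n_perm
    out.attrs["alpha"] = alpha
    return out
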