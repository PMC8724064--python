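"""Config-driven orchestration of the full analysis on a data bundle.

A :class:`RunConfig` names the per-cell-type replicate matrices, loop calls,
gene/expression/peak/signal files, the analysis resolutions and thresholds,
and a master seed. :func:`run_pipeline` executes matrix QC → compartments →
switches → classes → concordance → TADs → classification → CALs → aCAL
split → overlap tests → ChIP/expression summaries, writes every stage's
table under the output directory, and returns a result dictionary. Reruns
with the same config are bit-reproducible for all seeded stages.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip as chip_mod
from . import formats
from .compartments import (CompartmentTrack, assign_gene_compartment,
                           call_compartments, cluster_compartment_classes,
                           compartment_intervals, detect_switches,
                           expression_orientation_track, gene_concordance_test,
                           gene_density_track, switching_bins)
from .contacts import (ContactMap, cis_short_fraction, contact_probability,
                       correlation_matrix, ice_normalize,
                       observed_over_expected, read_bins_bed,
                       read_contact_map, replicate_correlation)
from .genome import BinnedGenome
from .loops import (LoopSet, apa_score, genes_in_loops, identify_cals,
                    peak_overlap_test, read_loops_bedpe, split_cals_by_class)
from .tads import call_tads, classify_tads, insulation_score, tad_genome_coverage, tad_metaprofile

logger = logging.getLogger("calscope.pipeline")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "run_bundle"]

_DEFAULT_RESOLUTIONS = {"compartment": 400_000, "tad": 40_000, "insulation": 40_000}
_DEFAULT_THRESHOLDS = {"alpha": 0.01, "stable": 0.70, "max_boundary": 400_000}
_DEFAULT_PARAMETERS = {
    "n_perm": 1000,
    "di_window": 2_000_000,
    "is_window": 500_000,
    "apa_flank_bins": 5,
    "n_shuffles": 10,
    "pseudocount": 0.5,
    "max_qc_dist": 2_000_000,
    "hmm_restarts": 5,
    "kmeans_restarts": 50,
    "cis_thresholds": [20_000, 40_000, 80_000, 100_000, 120_000],
}

_KNOWN_KEYS = {
    "cell_types", "matrices", "bins_bed", "loops", "genes", "expression",
    "peaks", "signal_treatment", "signal_input", "resolutions", "thresholds",
    "parameters", "seed", "outdir",
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    cell_types: list[str]
    matrices: dict[str, list[Path]]  # cell type -> replicate matrix paths
    bins_bed: Path
    loops: dict[str, Path]
    genes: Path
    expression: Path
    peaks: Path
    signal_treatment: Path
    signal_input: Path
    outdir: Path
    resolutions: dict = field(default_factory=lambda: dict(_DEFAULT_RESOLUTIONS))
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    parameters: dict = field(default_factory=lambda: dict(_DEFAULT_PARAMETERS))
    seed: int = 0

    @property
    def reference_cell(self) -> str:
        return self.cell_types[0]


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, reporting all problems at once."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    problems: list[str] = []
    for k in raw:
        if k not in _KNOWN_KEYS:
            problems.append(f"unknown key: {k!r}")
    required = ["cell_types", "matrices", "bins_bed", "loops", "genes",
                "expression", "peaks", "signal_treatment", "signal_input",
                "outdir"]
    for k in required:
        if k not in raw:
            problems.append(f"missing required key: {k!r}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))

    base = path.parent

    def _p(v) -> Path:
        q = Path(v)
        return q if q.is_absolute() else base / q

    cell_types = list(raw["cell_types"])
    matrices = {ct: [_p(m) for m in ms] for ct, ms in raw["matrices"].items()}
    loops = {ct: _p(v) for ct, v in raw["loops"].items()}
    cfg = RunConfig(
        cell_types=cell_types,
        matrices=matrices,
        bins_bed=_p(raw["bins_bed"]),
        loops=loops,
        genes=_p(raw["genes"]),
        expression=_p(raw["expression"]),
        peaks=_p(raw["peaks"]),
        signal_treatment=_p(raw["signal_treatment"]),
        signal_input=_p(raw["signal_input"]),
        outdir=_p(raw["outdir"]),
        seed=int(raw.get("seed", 0)),
    )
    cfg.resolutions.update(raw.get("resolutions", {}))
    cfg.thresholds.update(raw.get("thresholds", {}))
    cfg.parameters.update(raw.get("parameters", {}))

    for ct in cell_types:
        if ct not in matrices:
            problems.append(f"cell type {ct!r} has no matrices entry")
        else:
            for m in matrices[ct]:
                if not m.exists():
                    problems.append(f"matrix not found: {m}")
    if cfg.reference_cell not in loops:
        problems.append(f"no loop file for reference cell {cfg.reference_cell!r}")
    for key in ("bins_bed", "genes", "expression", "peaks",
                "signal_treatment", "signal_input"):
        p = getattr(cfg, key)
        if not p.exists():
            problems.append(f"{key} not found: {p}")
    if not (0 < cfg.thresholds["alpha"] < 1):
        problems.append(f"alpha must be in (0,1), got {cfg.thresholds['alpha']}")
    if not (0 < cfg.thresholds["stable"] <= 1):
        problems.append(f"stable threshold must be in (0,1], got {cfg.thresholds['stable']}")
    for name, r in cfg.resolutions.items():
        if r <= 0:
            problems.append(f"resolution {name} must be positive")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return cfg


def config_for_bundle(bundle_dir: str | Path, outdir: str | Path,
                      seed: int = 0, **overrides) -> RunConfig:
    """Build a RunConfig directly from a fixture-bundle manifest."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    cts = manifest["cell_types"]
    cfg = RunConfig(
        cell_types=cts,
        matrices={ct: [bundle_dir / m for m in manifest["matrices"][ct]]
                  for ct in cts},
        bins_bed=bundle_dir / "bins.bed",
        loops={ct: bundle_dir / f"loops_{ct}.bedpe" for ct in cts},
        genes=bundle_dir / "genes.bed",
        expression=bundle_dir / "expression.tsv",
        peaks=bundle_dir / "peaks.bed",
        signal_treatment=bundle_dir / "signal_treatment.bedgraph",
        signal_input=bundle_dir / "signal_input.bedgraph",
        outdir=Path(outdir),
        seed=seed,
    )
    cfg.parameters.update(overrides.pop("parameters", {}))
    cfg.resolutions.update(overrides.pop("resolutions", {}))
    cfg.thresholds.update(overrides.pop("thresholds", {}))
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    return cfg


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _compartment_track(raw: ContactMap, factor: int, orientation,
                       cell_type: str, replicate: str) -> CompartmentTrack:
    coarse = raw.coarsen(factor) if factor > 1 else raw
    bal = ice_normalize(coarse)
    corr = correlation_matrix(observed_over_expected(bal))
    return call_compartments(corr, orientation, cell_type=cell_type,
                             replicate=replicate)


def _read_signal(cfg: RunConfig) -> chip_mod.SignalTrack:
    t = formats.read_bedgraph(cfg.signal_treatment)
    i = formats.read_bedgraph(cfg.signal_input)
    names = list(dict.fromkeys(t["chrom"]))
    lengths = [int(t.loc[t["chrom"] == c, "end"].max()) for c in names]
    bs = int((t["end"] - t["start"]).max())
    g = BinnedGenome(tuple(names), tuple(lengths), bs)
    treatment = {c: t.loc[t["chrom"] == c, "value"].to_numpy() for c in names}
    inp = {c: i.loc[i["chrom"] == c, "value"].to_numpy() for c in names}
    return chip_mod.SignalTrack(genome=g, treatment=treatment, input_=inp)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns a result dict and writes outputs."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": {"seed": cfg.seed, "cell_types": cfg.cell_types,
                                "resolutions": dict(cfg.resolutions),
                                "thresholds": dict(cfg.thresholds)}}
    stage = "load"
    try:
        genome = read_bins_bed(cfg.bins_bed)
        ref = cfg.reference_cell
        raws = {ct: [read_contact_map(p, genome) for p in cfg.matrices[ct]]
                for ct in cfg.cell_types}
        merged = {ct: sum(reps[1:], start=reps[0]) for ct, reps in raws.items()}
        genes = formats.read_bed(cfg.genes)
        expr = pd.read_csv(cfg.expression, sep="\t", index_col=0)
        peaks = formats.read_bed(cfg.peaks)
        signal = _read_signal(cfg)

        # --- stage: matrix QC -------------------------------------------
        stage = "matrix_qc"
        logger.info("stage %s", stage)
        qc = {}
        for ct, reps in raws.items():
            if len(reps) >= 2:
                qc[ct] = replicate_correlation(
                    reps[0], reps[1], max_dist=cfg.parameters["max_qc_dist"])
        results["replicate_correlation"] = qc
        cis = cis_short_fraction(merged[ref], cfg.parameters["cis_thresholds"])
        cis.to_csv(out / "cis_short_fraction.tsv", sep="\t", index=False)
        results["cis_short_fraction"] = cis
        ps = contact_probability(merged[ref])
        ps.to_frame().to_csv(out / "contact_probability.tsv", sep="\t", index=False)
        results["ps_slope"] = ps.loglog_slope()

        # --- stage: compartments ----------------------------------------
        stage = "compartments"
        logger.info("stage %s", stage)
        factor = cfg.resolutions["compartment"] // genome.bin_size
        comp_genome = genome.coarsen(factor) if factor > 1 else genome
        density = gene_density_track(genes, comp_genome)
        tracks_merged: dict[str, CompartmentTrack] = {}
        tracks_reps: dict[str, list[CompartmentTrack]] = {}
        for ct in cfg.cell_types:
            # orient by the cell type's own expression when available:
            # gene density is static and can anti-correlate with PC1 in a
            # cell type whose compartments switched extensively
            if ct in expr.columns:
                orientation = expression_orientation_track(
                    genes, expr[ct], comp_genome)
            else:
                orientation = density
            tracks_merged[ct] = _compartment_track(
                merged[ct], factor, orientation, ct, "merged")
            tracks_reps[ct] = [
                _compartment_track(r, factor, orientation, ct, f"rep{k+1}")
                for k, r in enumerate(raws[ct])]
        comp_df = tracks_merged[ref].to_frame()
        for ct in cfg.cell_types:
            comp_df[f"pc1_{ct}"] = tracks_merged[ct].pc1_flat()
            comp_df[f"label_{ct}"] = tracks_merged[ct].label_flat()
        comp_df.to_csv(out / "compartments.tsv", sep="\t", index=False)
        results["tracks_merged"] = tracks_merged

        # --- stage: switches --------------------------------------------
        stage = "switches"
        logger.info("stage %s", stage)
        switches = detect_switches(tracks_reps, ref)
        switches.to_csv(out / "switches.tsv", sep="\t", index=False)
        results["switches"] = switches

        # --- stage: compartment classes ---------------------------------
        stage = "compartment_classes"
        logger.info("stage %s", stage)
        sw_bins = switching_bins(switches)
        profiles = []
        for _, row in sw_bins.iterrows():
            rec = {"chrom": row["chrom"], "bin": row["bin"]}
            for ct in cfg.cell_types:
                rec[ct] = tracks_merged[ct].pc1[row["chrom"]][row["bin"]]
            profiles.append(rec)
        classes = pd.DataFrame(
            profiles, columns=["chrom", "bin"] + cfg.cell_types)
        if len(classes) >= 2:
            clustered = cluster_compartment_classes(
                classes[cfg.cell_types], ref, seed=cfg.seed,
                n_restarts=cfg.parameters["kmeans_restarts"])
            classes["compartment_class"] = clustered["compartment_class"].values
        else:
            classes["compartment_class"] = pd.Series(dtype=object)
            warnings.warn("fewer than 2 switching bins; class clustering skipped",
                          RuntimeWarning)
        classes.to_csv(out / "compartment_classes.tsv", sep="\t", index=False)
        results["classes"] = classes

        # --- stage: concordance -----------------------------------------
        stage = "concordance"
        logger.info("stage %s", stage)
        expr_in = expr[[ct for ct in cfg.cell_types if ct in expr.columns]].copy()
        expr_in.attrs["genes"] = genes
        concordance = gene_concordance_test(
            expr_in, tracks_merged, n_perm=cfg.parameters["n_perm"],
            alpha=cfg.thresholds["alpha"], seed=cfg.seed)
        concordance.to_csv(out / "concordance.tsv", sep="\t")
        results["concordance"] = concordance

        # --- stage: TADs -------------------------------------------------
        stage = "tads"
        logger.info("stage %s", stage)
        tad_factor = cfg.resolutions["tad"] // genome.bin_size
        tad_sets = {}
        balanced = {}
        for ct in cfg.cell_types:
            m = merged[ct].coarsen(tad_factor) if tad_factor > 1 else merged[ct]
            bal = ice_normalize(m)
            balanced[ct] = bal
            tad_sets[ct], _ = call_tads(
                bal, window=cfg.parameters["di_window"], seed=cfg.seed,
                n_restarts=cfg.parameters["hmm_restarts"], cell_type=ct)
        tad_sets[ref].intervals.to_csv(out / "tads_reference.tsv", sep="\t",
                                       index=False)
        results["tads"] = tad_sets
        results["tad_coverage"] = {
            ct: tad_genome_coverage(ts, genome) for ct, ts in tad_sets.items()}
        ins = insulation_score(balanced[ref], window=cfg.parameters["is_window"])
        ins.to_frame().to_csv(out / "insulation_reference.tsv", sep="\t", index=False)
        results["insulation"] = ins
        results["tad_metaprofile"] = tad_metaprofile(ins, tad_sets[ref])
        tad_types = {}
        for ct in cfg.cell_types[1:]:
            tad_types[ct] = classify_tads(
                tad_sets[ref], tad_sets[ct],
                stable_threshold=cfg.thresholds["stable"])
        if tad_types:
            pd.concat(tad_types, names=["vs_cell"]).to_csv(
                out / "tad_types.tsv", sep="\t")
        results["tad_types"] = tad_types

        # --- stage: loops / CALs ----------------------------------------
        stage = "cals"
        logger.info("stage %s", stage)
        loops = read_loops_bedpe(cfg.loops[ref], cell_type=ref)
        apa_map = observed_over_expected(balanced[ref])
        apa = apa_score(apa_map, loops,
                        flank_bins=cfg.parameters["apa_flank_bins"])
        apa.to_frame().to_csv(out / "apa_matrix.tsv", sep="\t", index=False)
        results["apa"] = apa
        cals = identify_cals(loops, tracks_merged[ref])
        cals = split_cals_by_class(cals, classes, genes)
        cals.loops.to_csv(out / "cals.tsv", sep="\t", index=False)
        for name, idx in cals.gene_sets.items():
            pd.Series(sorted(idx)).to_csv(out / f"genes_{name}.tsv",
                                          sep="\t", index=False, header=False)
        results["cals"] = cals

        # --- stage: peak overlap ----------------------------------------
        stage = "peak_overlap"
        logger.info("stage %s", stage)
        acal_loops = cals.subset("activation")
        if len(acal_loops) and len(peaks):
            # anchor intervals, not full spans: at realistic peak densities a
            # multi-hundred-kb span (and any shuffled control of that length)
            # almost surely contains a peak, so span overlap saturates at 1
            regions = pd.concat([
                acal_loops[["chrom", "start1", "end1"]].rename(
                    columns={"start1": "start", "end1": "end"}),
                acal_loops[["chrom", "start2", "end2"]].rename(
                    columns={"start2": "start", "end2": "end"}),
            ], ignore_index=True)
            overlap = peak_overlap_test(
                regions, peaks, genome,
                n_shuffles=cfg.parameters["n_shuffles"], seed=cfg.seed)
        else:
            overlap = None
            warnings.warn("no aCALs or no peaks; overlap test skipped",
                          RuntimeWarning)
        results["peak_overlap"] = overlap

        # --- stage: ChIP / expression summaries -------------------------
        stage = "chip_rna"
        logger.info("stage %s", stage)
        sig = chip_mod.compartment_signal(
            signal, tracks_merged[ref],
            pseudocount=cfg.parameters["pseudocount"])
        sig.to_csv(out / "compartment_signal.tsv", sep="\t", index=False)
        results["compartment_signal"] = sig
        counts = chip_mod.peak_counts_by_compartment(peaks, tracks_merged[ref])
        counts.to_csv(out / "peak_counts.tsv", sep="\t", index=False)
        results["peak_counts"] = counts
        in_loops = genes_in_loops(genes, loops)
        cal_genes = cals.gene_sets["in_aCALs"].union(
            cals.gene_sets["in_repressed_CALs"])
        group = pd.Series("out_of_CALs", index=in_loops.index)
        group[in_loops] = "loops_only"
        group[group.index.isin(cal_genes)] = "in_CALs"
        if ref in expr.columns and group.nunique() >= 2:
            expr_cmp = chip_mod.compare_expression_groups(expr[ref], group)
            expr_cmp.to_csv(out / "expression_groups.tsv", sep="\t", index=False)
            results["expression_groups"] = expr_cmp

        # --- manifest / report ------------------------------------------
        stage = "report"
        manifest = {
            "seed": cfg.seed,
            "cell_types": cfg.cell_types,
            "resolutions": dict(cfg.resolutions),
            "thresholds": dict(cfg.thresholds),
            "parameters": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                           for k, v in cfg.parameters.items()},
            "outputs": sorted(p.name for p in out.glob("*.tsv")),
            "n_loops": len(loops),
            "n_cals": int(cals.loops["is_cal"].sum()),
            "n_acal_genes": len(cals.gene_sets["in_aCALs"]),
            "n_repressed_cal_genes": len(cals.gene_sets["in_repressed_CALs"]),
            "n_concordant_genes": int(concordance["concordant"].sum()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        _write_report(out / "report.md", results, manifest)
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_report(path: Path, results: dict, manifest: dict) -> None:
    lines = ["# calscope pipeline report", ""]
    lines.append("## Matrix QC")
    for ct, r in results.get("replicate_correlation", {}).items():
        lines.append(f"- replicate correlation {ct}: {r:.4f}")
    lines.append(f"- p(s) log-log slope: {results.get('ps_slope', float('nan')):.3f}")
    lines.append("")
    lines.append("## Compartments")
    sw = results.get("switches")
    if sw is not None and len(sw):
        frac = (sw["direction"].isin(["A->B", "B->A"])).mean()
        lines.append(f"- switching bin fraction: {frac:.3f}")
    conc = results.get("concordance")
    if conc is not None:
        lines.append(f"- concordant genes: {int(conc['concordant'].sum())} / {len(conc)}")
    lines.append("")
    lines.append("## TADs")
    for ct, cov in results.get("tad_coverage", {}).items():
        lines.append(f"- TAD genome coverage {ct}: {cov:.3f}")
    lines.append("")
    lines.append("## Loops / CALs")
    apa = results.get("apa")
    if apa is not None:
        lines.append(f"- APA score: {apa.score:.3f} ({apa.n_loops_used} loops)")
    lines.append(f"- CALs: {manifest['n_cals']} of {manifest['n_loops']} loops")
    lines.append(f"- genes in aCALs: {manifest['n_acal_genes']}; "
                 f"in repressed CALs: {manifest['n_repressed_cal_genes']}")
    ov = results.get("peak_overlap")
    if ov:
        lines.append(f"- aCAL peak overlap: {ov['overlap_fraction']:.3f} "
                     f"(OR {ov['odds_ratio']:.2f}, p {ov['p_value']:.3g})")
    path.write_text("\n".join(lines) + "\n")


def run_bundle(bundle_dir: str | Path, outdir: str | Path, seed: int = 0,
               **overrides) -> dict:
    """Convenience: run the full pipeline on a fixture bundle directory."""
    cfg = config_for_bundle(bundle_dir, outdir, seed=seed, **overrides)
    return run_pipeline(cfg)
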