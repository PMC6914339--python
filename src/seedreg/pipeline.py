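"""End-to-end orchestration: simulate or load data, run every analysis
stage, and write TSV/BED/plot outputs plus a run manifest.

When truth tables from the synthetic generator are present, a recovery
report is added: target-gene recall and false-target rate, H3K27me3
cluster agreement (adjusted Rand index), imprinting-call accuracy, and the
permutation p-value for the planted RC/Helitron enrichment.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from . import io as sio
from .enrichment import categorize_flanking_genes
from .homology import homology_clusters
from .imprinting import calls_table, classify_imprinting, parental_ratio
from .intervals import GenomicInterval, IntervalSet, intersect
from .motifs import Motif, motif_density, scan_consensus
from .peaks import annotate_sites, annotation_table, call_targets, common_peaks
from .permutation import permutation_test, results_table
from .profiles import bin_signal, cluster_sites, plot_heatmap, plot_metagene
from .simulate import SimulationConfig, simulate_bundle, write_bundle

STAGES = ("peaks", "targets", "motifs", "te_overlap", "clusters", "enrich",
          "profiles", "imprinting")


@dataclass
class PipelineConfig:
    outdir: str = "seedreg_run"
    seed: int = 0
    simulate: SimulationConfig | None = field(
        default_factory=SimulationConfig)
    inputs: dict = field(default_factory=dict)  # used when simulate is None
    n_permutations: int = 10_000
    promoter_span: int = 3000
    target_upstream: int = 1500
    target_downstream: int = 500
    signal_window: int = 2000
    signal_bin: int = 50
    k_profiles: int = 2
    imprinting_fold: float = 4.0
    min_informative_reads: int = 10
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulate", None)
        cfg = cls(**data)
        if sim is None:
            cfg.simulate = None
        else:
            cfg.simulate = SimulationConfig.from_dict(sim or {})
        if cfg.simulate is None:
            required = {"genome", "genes", "tes", "peaks_rep1", "peaks_rep2"}
            missing = required - set(cfg.inputs)
            if missing:
                raise ValueError(f"inputs missing: {sorted(missing)}")
            for name, path_ in cfg.inputs.items():
                if not os.path.exists(path_):
                    raise FileNotFoundError(f"input {name}: {path_}")
        return cfg


def _read_te_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                continue
            rows.append(
                {"te_id": f[3], "chrom": f[0], "start": int(f[1]),
                 "end": int(f[2]),
                 "superfamily": f[6] if len(f) > 6 else "TE",
                 "family": f[7] if len(f) > 7 else f[3]}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dictionary."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    manifest = {
        "package": "seedreg",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "n_permutations": config.n_permutations,
            "promoter_span": config.promoter_span,
            "target_window": [config.target_upstream, config.target_downstream],
            "signal_window": config.signal_window,
            "signal_bin": config.signal_bin,
            "k_profiles": config.k_profiles,
            "imprinting_fold": config.imprinting_fold,
            "min_informative_reads": config.min_informative_reads,
        },
        "stages": [],
        "outputs": {},
    }

    def record(stage, **files):
        manifest["stages"].append(stage)
        manifest["outputs"].update(files)

    truth = {}
    try:
        # --- inputs ---------------------------------------------------
        if config.simulate is not None:
            sim_cfg = config.simulate
            sim_cfg.seed = config.seed
            bundle = simulate_bundle(sim_cfg)
            data_dir = os.path.join(out, "data")
            paths = write_bundle(bundle, data_dir)
            record("simulate",
                   **{f"data/{k}": os.path.relpath(v, out)
                      for k, v in paths.items()})
            genome = bundle.annotation.genome
            genes = bundle.annotation.genes
            te_table = bundle.annotation.te_table
            rep1, rep2 = bundle.peaks.rep1, bundle.peaks.rep2
            counts = bundle.allelic.counts
            tracks = bundle.allelic.tracks
            truth = {
                "peaks": bundle.peaks.truth,
                "genes": bundle.allelic.gene_truth,
                "sites": bundle.allelic.site_truth,
            }
        else:
            inp = config.inputs
            genome = sio.read_fasta(inp["genome"])
            genes = sio.read_gene_models(inp["genes"])
            te_table = _read_te_bed(inp["tes"])
            rep1 = sio.parse_bed(inp["peaks_rep1"])
            rep2 = sio.parse_bed(inp["peaks_rep2"])
            counts = sio.read_tsv(inp["counts"]) if "counts" in inp else None
            tracks = {
                name: sio.read_bedgraph(path)
                for name, path in inp.get("tracks", {}).items()
            }

        te_by_sf = {
            sf: IntervalSet(
                GenomicInterval(r.chrom, r.start, r.end, ".", r.te_id)
                for r in sub.itertuples(index=False))
            for sf, sub in te_table.groupby("superfamily")
        }
        promoters = IntervalSet(
            p for g in genes
            if (p := g.promoter(config.promoter_span)) is not None
            and p.end <= len(genome.get(g.chrom, ""))
        )

        # --- binding sites --------------------------------------------
        site_set = common_peaks(rep1, rep2)
        sio.write_bed(site_set.sites, os.path.join(out, "binding_sites.bed"))
        sio.write_tsv(
            pd.DataFrame(
                [{"replicate": k, "fraction_overlapping_other": v}
                 for k, v in sorted(site_set.reproducibility.items())]),
            os.path.join(out, "reproducibility.tsv"))
        record("peaks", binding_sites="binding_sites.bed",
               reproducibility="reproducibility.tsv")

        # --- annotation and targets -----------------------------------
        annotations = annotate_sites(site_set, genes, config.promoter_span)
        ann_df = annotation_table(annotations)
        sio.write_tsv(ann_df, os.path.join(out, "site_annotation.tsv"))
        targets = call_targets(annotations, config.target_upstream,
                               config.target_downstream)
        sio.write_tsv(pd.DataFrame({"gene_id": sorted(targets)}),
                      os.path.join(out, "target_genes.tsv"))
        record("targets", site_annotation="site_annotation.tsv",
               target_genes="target_genes.tsv")

        # --- motif scan and density -----------------------------------
        motif = Motif()
        matches = scan_consensus(genome, motif)
        match_ivs = [m.interval for m in matches]
        sio.write_bed(match_ivs, os.path.join(out, "motif_matches.bed"))
        density_classes = dict(te_by_sf)
        density_classes["promoters"] = promoters
        density, chi2 = motif_density(density_classes, matches, len(motif))
        sio.write_tsv(density, os.path.join(out, "motif_density.tsv"))
        sio.write_tsv(chi2, os.path.join(out, "motif_density_chi2.tsv"))
        record("motifs", motif_matches="motif_matches.bed",
               motif_density="motif_density.tsv",
               motif_density_chi2="motif_density_chi2.tsv")

        # --- TE overlap permutation test ------------------------------
        perm = permutation_test(
            site_set.sites, te_by_sf, promoters,
            n_iter=config.n_permutations, seed=config.seed)
        perm_df = results_table(perm)
        sio.write_tsv(perm_df, os.path.join(out, "te_overlap.tsv"))
        record("te_overlap", te_overlap="te_overlap.tsv")

        # --- homology clusters of motif-carrying TEs ------------------
        te_seqs, te_motif_spans = {}, {}
        for r in te_table.itertuples(index=False):
            seq = genome[r.chrom][r.start:r.end]
            hits = [m for m in scan_consensus({r.te_id: seq}, motif)
                    if m.match_class == "perfect"]
            if hits:
                te_seqs[r.te_id] = seq
                te_motif_spans[r.te_id] = (hits[0].start, hits[0].end)
        if len(te_seqs) >= 2:
            pair_df, clusters = homology_clusters(te_seqs, te_motif_spans)
        else:
            pair_df = pd.DataFrame()
            clusters = {k: k for k in te_seqs}
        sio.write_tsv(pair_df, os.path.join(out, "homology_pairs.tsv"))
        cluster_df = pd.DataFrame(
            sorted(clusters.items()), columns=["te_id", "cluster"])
        sio.write_tsv(cluster_df, os.path.join(out, "homology_clusters.tsv"))
        record("clusters", homology_pairs="homology_pairs.tsv",
               homology_clusters="homology_clusters.tsv")

        # --- gene categories (promoter Helitron / motif / binding) ----
        helitrons = te_by_sf.get("RC/Helitron", IntervalSet())
        categories = categorize_flanking_genes(
            genes, helitrons, matches, site_set.sites, config.promoter_span)
        cat_df = pd.DataFrame(sorted(categories.items()),
                              columns=["gene_id", "category"])
        sio.write_tsv(cat_df, os.path.join(out, "gene_categories.tsv"))
        record("enrich", gene_categories="gene_categories.tsv")

        # --- allelic chromatin profiles -------------------------------
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        profile_files = {}
        binned = {}
        for channel in ("h3k27me3_maternal", "h3k27me3_paternal",
                        "h3k27me3_total"):
            if channel not in tracks:
                continue
            binned[channel] = bin_signal(
                tracks[channel], site_set.sites, config.signal_window,
                config.signal_bin, chrom_sizes)
            meta = binned[channel].metagene
            path = os.path.join(out, f"metagene_{channel}.tsv")
            sio.write_tsv(
                pd.DataFrame({"bin_offset": meta.index, "mean_signal":
                              meta.to_numpy()}), path)
            profile_files[f"metagene_{channel}"] = f"metagene_{channel}.tsv"
        profile_labels = None
        if "h3k27me3_total" in binned:
            profile_labels, _ = cluster_sites(
                binned["h3k27me3_total"], k=config.k_profiles,
                seed=config.seed)
            lab_df = profile_labels.rename_axis("site").reset_index()
            sio.write_tsv(lab_df, os.path.join(out, "profile_clusters.tsv"))
            profile_files["profile_clusters"] = "profile_clusters.tsv"
            if config.make_plots:
                plot_metagene(
                    {c: b.metagene for c, b in binned.items()},
                    os.path.join(out, "metagene.svg"))
                plot_heatmap(binned["h3k27me3_total"], profile_labels,
                             os.path.join(out, "heatmap.svg"))
                profile_files.update(metagene_plot="metagene.svg",
                                     heatmap_plot="heatmap.svg")
        record("profiles", **profile_files)

        # --- imprinting calls -----------------------------------------
        imprint_files = {}
        calls = None
        if counts is not None:
            fractions = parental_ratio(counts, config.min_informative_reads)
            calls, summary = classify_imprinting(fractions,
                                                 config.imprinting_fold)
            call_df = calls_table(calls)
            sio.write_tsv(call_df, os.path.join(out, "imprinting_calls.tsv"))
            sio.write_tsv(summary,
                          os.path.join(out, "imprinting_2x_vs_3x.tsv"))
            imprint_files = {"imprinting_calls": "imprinting_calls.tsv",
                             "imprinting_2x_vs_3x": "imprinting_2x_vs_3x.tsv"}
        record("imprinting", **imprint_files)

        # --- recovery against planted truth ---------------------------
        if truth:
            report = _recovery_report(
                truth, targets, perm_df, site_set, profile_labels,
                calls, clusters, te_table)
            with open(os.path.join(out, "recovery_report.json"), "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            manifest["outputs"]["recovery_report"] = "recovery_report.json"
            manifest["recovery"] = report
    except Exception as exc:
        with open(os.path.join(out, "FAILED"), "w") as fh:
            fh.write(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(
            f"pipeline failed at stage "
            f"{manifest['stages'][-1] if manifest['stages'] else 'input'}: {exc}"
        ) from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _recovery_report(truth, targets, perm_df, site_set, profile_labels,
                     calls, clusters, te_table) -> dict:
    report = {}
    truth_targets = set(truth["peaks"]["target_gene"])
    called = set(targets)
    report["target_recall"] = (
        len(called & truth_targets) / len(truth_targets) if truth_targets else
        float("nan"))
    report["false_target_rate"] = (
        len(called - truth_targets) / len(called) if called else 0.0)

    hel = perm_df[perm_df["feature"] == "RC/Helitron"]
    if len(hel):
        report["helitron_permutation_p"] = float(hel["p_value"].iloc[0])
        report["helitron_z_score"] = float(hel["z_score"].iloc[0])
        report["helitron_observed_overlap"] = float(
            hel["observed_overlap"].iloc[0])
        report["helitron_null_mean_overlap"] = float(hel["null_mean"].iloc[0])

    # profile clusters: match analysis sites to truth peaks by overlap
    if profile_labels is not None and len(truth["sites"]):
        tp = truth["peaks"].merge(truth["sites"], on="peak_id")
        peak_ivs = IntervalSet(
            GenomicInterval(r.chrom, max(0, r.center - r.length // 2),
                            max(0, r.center - r.length // 2) + r.length, ".",
                            r.peak_id)
            for r in tp.itertuples(index=False))
        arch = dict(zip(tp["peak_id"], tp["archetype"]))
        hits: dict[str, set[str]] = {}
        for site, peak, _ in intersect(site_set.sites, peak_ivs):
            hits.setdefault(site.name, set()).add(arch[peak.name])
        # score only sites matching truth peaks of one unambiguous archetype
        site_arch = {s: next(iter(a)) for s, a in hits.items() if len(a) == 1}
        shared = [s for s in profile_labels.index if s in site_arch]
        if shared:
            report["profile_cluster_ari"] = float(adjusted_rand_score(
                [site_arch[s] for s in shared],
                [int(profile_labels[s]) for s in shared]))

    if calls is not None and len(truth["genes"]):
        truth_map = {(r.gene_id, r.cross): r.label
                     for r in truth["genes"].itertuples(index=False)}
        scored = [(c, truth_map[(c.gene_id, c.cross)]) for c in calls
                  if (c.gene_id, c.cross) in truth_map
                  and c.label != "insufficient_data"]
        if scored:
            report["imprinting_accuracy"] = float(
                np.mean([c.label == t for c, t in scored]))

    carriers = set(te_table.loc[te_table.get("motif_carrier", False) == True,
                                "te_id"]) if "motif_carrier" in te_table else set()
    if clusters and carriers:
        sizes = pd.Series(list(clusters.values())).value_counts()
        report["homology_n_clusters"] = int(len(sizes))
        report["homology_largest_cluster"] = int(sizes.iloc[0])
        largest = sizes.index[0]
        members = {k for k, v in clusters.items() if v == largest}
        report["homology_largest_cluster_carrier_fraction"] = float(
            len(members & carriers) / len(members))
    return report
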