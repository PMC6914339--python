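"""Synthetic dataset generator with machine-readable planted truth.

Emulates the statistical structure of an endosperm TF-binding study on a
small genome: genes with 3-kb promoters, TE copies of several
superfamilies, a subset of RC/Helitron copies carrying a planted perfect
CArG-box whose copies within a family descend from one mutated ancestor,
two-replicate ChIP peak sets enriched at motif-carrying promoter TEs,
beta-binomially dispersed maternal/paternal read counts with planted
MEG/PEG labels under 2x and 3x-paternal-excess expectations, and two
planted allele-specific H3K27me3 archetypes (flank-enriched with a
depleted center versus flat-depleted).

One seed governs the whole bundle; rerunning with the same configuration
produces byte-identical files. The background sequence is scrubbed of
chance perfect motifs (and of chance nearly-perfect motifs inside TE
copies), so that motif occurrences inside TEs are exactly the planted
ones.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .imprinting import CROSS_2X, CROSS_3X, EXPECTED_MATERNAL_FRACTION
from .intervals import GenomicInterval, GeneModel, IntervalSet
from .motifs import Motif, _window_distances

PLANTED_MOTIF = "CCAAATATGG"  # one concrete word of the CC(A/T)6GG class
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 1_200_000
    n_genes: int = 200
    gene_length: tuple[int, int] = (800, 2000)
    promoter_length: int = 3000
    te_counts: dict = field(
        default_factory=lambda: {"RC/Helitron": 120, "LTR/Gypsy": 90,
                                 "DNA/MuDR": 90}
    )
    te_length: tuple[int, int] = (150, 400)
    helitron_motif_fraction: float = 0.5
    helitron_family_size: int = 20
    substitution_rate: float = 0.05
    promoter_te_fraction: float = 0.5
    peak_count: int = 150
    peak_length: tuple[int, int] = (150, 300)
    replicate_jitter: int = 50
    replicate_specific_fraction: float = 0.1
    peak_motif_targeting: float = 0.4
    n_expressed_genes: int = 150
    meg_fraction: float = 0.15
    peg_fraction: float = 0.15
    allelic_dispersion: float = 0.02
    depth_range: tuple[int, int] = (200, 400)
    n_replicates: int = 2
    label_margin: float = 1.5  # planted odds deviation = fold ** label_margin
    imprinting_fold: float = 4.0
    signal_window: int = 2000
    signal_bin: int = 50
    flank_amplitude: float = 2.0
    center_depletion_bins: int = 10
    signal_baseline: float = 0.2
    signal_noise_sd: float = 1.0
    cluster1_fraction: float = 0.5
    meth_baseline: float = 0.2
    meth_meg_paternal_boost: float = 0.3
    meth_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("helitron_motif_fraction", "promoter_te_fraction",
                     "peak_motif_targeting", "replicate_specific_fraction",
                     "meg_fraction", "peg_fraction", "cluster1_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.meg_fraction + self.peg_fraction > 1.0:
            raise ValueError("meg_fraction + peg_fraction exceed 1")
        if min(self.chrom_length, self.promoter_length, self.n_genes) <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.peak_length[1] > self.promoter_length:
            raise ValueError("peaks longer than the promoter cannot be placed")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        kwargs = dict(data)
        for key in ("gene_length", "te_length", "peak_length", "depth_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class SyntheticAnnotation:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    te_table: pd.DataFrame  # te_id chrom start end superfamily family
    #                         motif_carrier motif_start motif_end host_gene

    @property
    def te_intervals(self) -> IntervalSet:
        return IntervalSet(
            GenomicInterval(r.chrom, r.start, r.end, ".", r.te_id)
            for r in self.te_table.itertuples(index=False)
        )

    def te_by_superfamily(self) -> dict[str, IntervalSet]:
        return {
            sf: IntervalSet(
                GenomicInterval(r.chrom, r.start, r.end, ".", r.te_id)
                for r in sub.itertuples(index=False)
            )
            for sf, sub in self.te_table.groupby("superfamily")
        }

    def promoters(self) -> IntervalSet:
        ivs = []
        for g in self.genes:
            p = g.promoter(self.config.promoter_length)
            if p is not None and p.end <= len(self.genome[g.chrom]):
                ivs.append(p)
        return IntervalSet(ivs)


@dataclass
class SyntheticPeaks:
    rep1: IntervalSet
    rep2: IntervalSet
    truth: pd.DataFrame  # peak_id chrom center length target_gene on_motif_te


@dataclass
class SyntheticAllelic:
    counts: pd.DataFrame  # gene_id cross replicate maternal paternal
    gene_truth: pd.DataFrame  # gene_id cross label
    site_truth: pd.DataFrame  # peak_id archetype
    tracks: dict[str, pd.DataFrame]  # chrom start end value per channel


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


# --- annotation ------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> SyntheticAnnotation:
    rng = _stage_rng(config.seed, 0)
    motif = Motif()
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    genome = {
        c: rng.integers(0, 4, size=config.chrom_length).astype(np.uint8)
        for c in chrom_names
    }

    # genes on an even grid, one per slot, promoter fitting inside the slot
    genes: list[GeneModel] = []
    per_chrom = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    per_chrom[: config.n_genes % config.n_chrom] += 1
    gmin, gmax = config.gene_length
    for ci, chrom in enumerate(chrom_names):
        n_c = int(per_chrom[ci])
        if n_c == 0:
            continue
        slot = config.chrom_length // n_c
        if slot < config.promoter_length + gmax + 100:
            raise ValueError(
                f"chromosome of {config.chrom_length} bp cannot hold {n_c} "
                f"genes with {config.promoter_length}-bp promoters"
            )
        for j in range(n_c):
            slot_start = j * slot
            length = int(rng.integers(gmin, gmax + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            slack = slot - config.promoter_length - length
            offset = int(rng.integers(0, max(1, slack // 2)))
            if strand == "+":
                body_start = slot_start + config.promoter_length + offset
            else:
                body_start = slot_start + slot - config.promoter_length - length - offset
            gene_id = f"gene_{len(genes):04d}"
            body = GenomicInterval(chrom, body_start, body_start + length,
                                   strand, gene_id)
            genes.append(GeneModel(gene_id, body, strand))

    te_rows = _place_tes(config, rng, genes)
    _write_te_sequences(config, rng, genome, te_rows)
    _scrub_chance_motifs(genome, te_rows, motif)
    ann = SyntheticAnnotation(
        config,
        {c: _decode(genome[c]) for c in chrom_names},
        genes,
        pd.DataFrame(te_rows),
    )
    return ann


def _place_tes(config: SimulationConfig, rng, genes):
    tmin, tmax = config.te_length
    superfamilies = sorted(config.te_counts)
    n_helitron = config.te_counts.get("RC/Helitron", 0)
    n_carriers = round(config.helitron_motif_fraction * n_helitron)

    te_rows = []
    te_specs = []  # (superfamily, carrier_flag)
    for sf in superfamilies:
        n_sf = config.te_counts[sf]
        for i in range(n_sf):
            carrier = sf == "RC/Helitron" and i < n_carriers
            te_specs.append((sf, carrier))

    # carriers all live in promoters (the planted enrichment substrate);
    # a fraction of the rest joins them, one TE per promoter
    non_carriers = [s for s in te_specs if not s[1]]
    carriers = [s for s in te_specs if s[1]]
    n_prom_extra = round(config.promoter_te_fraction * len(non_carriers))
    promoter_specs = carriers + non_carriers[:n_prom_extra]
    intergenic_specs = non_carriers[n_prom_extra:]
    if len(promoter_specs) > len(genes):
        raise ValueError(
            f"{len(promoter_specs)} promoter TEs requested but only "
            f"{len(genes)} gene promoters available"
        )
    host_idx = rng.choice(len(genes), size=len(promoter_specs), replace=False)

    # family assignment for motif carriers: descendants of shared ancestors
    family_sizes = []
    remaining = len(carriers)
    while remaining > 0:
        size = min(config.helitron_family_size, remaining)
        family_sizes.append(size)
        remaining -= size
    carrier_families = [
        f"HELFAM{f + 1}" for f, size in enumerate(family_sizes)
        for _ in range(size)
    ]
    carrier_lengths = {
        f"HELFAM{f + 1}": int(rng.integers(max(tmin, 200), tmax + 1))
        for f in range(len(family_sizes))
    }

    counter = 0
    carrier_seen = 0
    blocked: dict[str, list[tuple[int, int]]] = {g.chrom: [] for g in genes}
    for g in genes:
        blocked[g.chrom].append((g.body.start, g.body.end))
        p = g.promoter(config.promoter_length)
        if p is not None:
            blocked[g.chrom].append((p.start, p.end))

    for spec_i, (sf, carrier) in enumerate(promoter_specs):
        gene = genes[int(host_idx[spec_i])]
        if carrier:
            family = carrier_families[carrier_seen]
            length = carrier_lengths[family]
            carrier_seen += 1
        else:
            family = f"{sf.split('/')[-1]}_solo_{counter}"
            length = int(rng.integers(tmin, tmax + 1))
        # proximal promoter placement: TE end within 1.5 kb upstream of TSS
        max_d = max(51, 1500 - length)
        d = int(rng.integers(50, max_d))
        if gene.strand == "+":
            end = gene.tss - d
            start = end - length
        else:
            start = gene.tss + 1 + d
            end = start + length
        start = max(0, start)
        te_rows.append(_te_row(counter, gene.chrom, start, end, sf, family,
                               carrier, length, gene.gene_id))
        blocked[gene.chrom].append((start, end))
        counter += 1

    # intergenic TEs go into the free gaps between blocked features
    gaps = _free_gaps(config, blocked)
    for sf, _ in intergenic_specs:
        length = int(rng.integers(tmin, tmax + 1))
        feasible = [i for i, (c, s, e) in enumerate(gaps) if e - s >= length]
        if not feasible:
            raise ValueError("genome too small to place all intergenic TEs")
        gi = int(feasible[rng.integers(0, len(feasible))])
        chrom, gs, ge = gaps.pop(gi)
        start = int(rng.integers(gs, ge - length + 1))
        te_rows.append(
            _te_row(counter, chrom, start, start + length, sf,
                    f"{sf.split('/')[-1]}_solo_{counter}", False, length, "")
        )
        counter += 1
        if start - gs > 0:
            gaps.append((chrom, gs, start))
        if ge - (start + length) > 0:
            gaps.append((chrom, start + length, ge))
        gaps.sort()
    return te_rows


def _te_row(i, chrom, start, end, sf, family, carrier, length, host_gene):
    motif_len = len(PLANTED_MOTIF)
    local = (length - motif_len) // 2
    return {
        "te_id": f"te_{i:04d}",
        "chrom": chrom,
        "start": int(start),
        "end": int(end),
        "superfamily": sf,
        "family": family,
        "motif_carrier": bool(carrier),
        "motif_start": int(start + local) if carrier else -1,
        "motif_end": int(start + local + motif_len) if carrier else -1,
        "host_gene": host_gene,
    }


def _free_gaps(config, blocked):
    gaps = []
    for chrom, spans in blocked.items():
        spans = sorted(spans)
        pos = 0
        for s, e in spans:
            if s > pos:
                gaps.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < config.chrom_length:
            gaps.append((chrom, pos, config.chrom_length))
    gaps.sort()
    return gaps


def _write_te_sequences(config, rng, genome, te_rows):
    """Motif-carrying families are mutated descendants of one ancestor."""
    motif_len = len(PLANTED_MOTIF)
    motif_codes = np.frombuffer(PLANTED_MOTIF.encode(), dtype=np.uint8)
    motif_codes = np.searchsorted(_BASES, motif_codes)
    ancestors: dict[str, np.ndarray] = {}
    for row in te_rows:
        if not row["motif_carrier"]:
            continue
        length = row["end"] - row["start"]
        family = row["family"]
        if family not in ancestors:
            seq = rng.integers(0, 4, size=length).astype(np.uint8)
            ancestors[family] = seq
        seq = ancestors[family].copy()
        # substitute outside the motif; the planted motif itself is conserved
        mutate = rng.random(length) < config.substitution_rate
        local = (length - motif_len) // 2
        mutate[local : local + motif_len] = False
        n_mut = int(mutate.sum())
        seq[mutate] = (seq[mutate] + rng.integers(1, 4, size=n_mut)) % 4
        seq[local : local + motif_len] = motif_codes
        genome[row["chrom"]][row["start"] : row["end"]] = seq


def _scrub_chance_motifs(genome, te_rows, motif: Motif, max_rounds: int = 20):
    """Remove chance motif hits: perfect everywhere, nearly perfect in TEs.

    Only the planted motif coordinates keep a perfect match, so downstream
    scans recover exactly the planted truth. Assumes the default motif,
    whose match class is its own reverse complement.
    """
    allowed = motif.allowed_matrix(False)
    length = len(motif)
    planted = {}
    te_masks = {}
    for chrom, seq in genome.items():
        planted[chrom] = np.zeros(len(seq), dtype=bool)
        te_masks[chrom] = np.zeros(len(seq), dtype=bool)
    for row in te_rows:
        te_masks[row["chrom"]][row["start"] : row["end"]] = True
        if row["motif_carrier"]:
            planted[row["chrom"]][row["motif_start"] : row["motif_end"]] = True
    for _ in range(max_rounds):
        dirty = False
        for chrom, seq in genome.items():
            dist = _window_distances(seq, allowed)
            perfect = np.flatnonzero(dist == 0)
            near = np.flatnonzero(dist == 1)
            near = near[te_masks[chrom][near]]
            for pos in np.concatenate([perfect, near]):
                window = slice(pos, pos + length)
                if planted[chrom][window].all():
                    continue  # the planted motif itself
                for j in range(length):
                    g = pos + j
                    if planted[chrom][g]:
                        continue
                    if allowed[j, seq[g]]:
                        seq[g] = int(np.flatnonzero(~allowed[j, :4])[0])
                        dirty = True
                        break
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# --- peaks -----------------------------------------------------------------

def simulate_peaks(
    annotation: SyntheticAnnotation, config: SimulationConfig | None = None
) -> SyntheticPeaks:
    config = config or annotation.config
    rng = _stage_rng(config.seed, 1)
    pmin, pmax = config.peak_length
    n_shared = round((1 - config.replicate_specific_fraction) * config.peak_count)
    n_specific = config.peak_count - n_shared
    n_on_motif = min(round(config.peak_motif_targeting * config.peak_count),
                     n_shared)

    carriers = annotation.te_table[annotation.te_table["motif_carrier"]]
    carriers = carriers[carriers["host_gene"] != ""]
    if n_on_motif > len(carriers):
        raise ValueError(
            f"{n_on_motif} motif-targeted peaks requested but only "
            f"{len(carriers)} motif-carrying promoter TEs exist"
        )
    chosen = carriers.iloc[
        np.sort(rng.choice(len(carriers), size=n_on_motif, replace=False))
    ]
    genes = {g.gene_id: g for g in annotation.genes}

    truth_rows = []
    for _, te in chosen.iterrows():
        center = (te["motif_start"] + te["motif_end"]) // 2
        length = int(rng.integers(pmin, pmax + 1))
        truth_rows.append((te["chrom"], int(center), length,
                           te["host_gene"], True))
    gene_ids = sorted(genes)
    for _ in range(n_shared - n_on_motif):
        gene = genes[gene_ids[int(rng.integers(0, len(gene_ids)))]]
        length = int(rng.integers(pmin, pmax + 1))
        # midpoint in the proximal promoter, inside the target-call window
        d = int(rng.integers(100, 1401))
        center = gene.tss - d if gene.strand == "+" else gene.tss + d
        truth_rows.append((gene.chrom, center, length, gene.gene_id, False))

    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "center", "length", "target_gene",
                             "on_motif_te"]
    ).sort_values(["chrom", "center"], kind="stable").reset_index(drop=True)
    truth.insert(0, "peak_id", [f"peak_{i:04d}" for i in range(len(truth))])

    def peak_interval(row, shift, tag):
        center = row.center + shift
        start = max(0, center - row.length // 2)
        return GenomicInterval(row.chrom, start, start + row.length, ".",
                               f"{row.peak_id}_{tag}")

    jit = config.replicate_jitter
    rep1, rep2 = [], []
    for row in truth.itertuples(index=False):
        rep1.append(peak_interval(row, 0, "r1"))
        shift = int(rng.integers(-jit, jit + 1)) if jit > 0 else 0
        rep2.append(peak_interval(row, shift, "r2"))
    # replicate-specific peaks: drawn independently for each replicate
    for rep, tag in ((rep1, "r1"), (rep2, "r2")):
        for i in range(n_specific):
            gene = genes[gene_ids[int(rng.integers(0, len(gene_ids)))]]
            length = int(rng.integers(pmin, pmax + 1))
            d = int(rng.integers(100, 1401))
            center = gene.tss - d if gene.strand == "+" else gene.tss + d
            start = max(0, center - length // 2)
            rep.append(GenomicInterval(gene.chrom, start, start + length, ".",
                                       f"spec_{tag}_{i:04d}"))
    return SyntheticPeaks(IntervalSet(rep1), IntervalSet(rep2), truth)


# --- allelic counts and tracks ---------------------------------------------

def _betabinom(rng, n, mu, rho):
    if rho <= 0:
        return int(rng.binomial(n, mu))
    a = mu * (1 / rho - 1)
    b = (1 - mu) * (1 / rho - 1)
    return int(rng.binomial(n, rng.beta(a, b)))


def planted_fraction(cross: str, label: str, fold: float, margin: float) -> float:
    """Mean maternal fraction planted for a label.

    Imprinted genes sit at a fold**margin deviation of the expected
    maternal:paternal odds, i.e. margin times the classifier boundary's
    deviation on the log-odds scale.
    """
    expected = EXPECTED_MATERNAL_FRACTION[cross]
    odds = expected / (1 - expected)
    if label == "MEG":
        odds *= fold ** margin
    elif label == "PEG":
        odds /= fold ** margin
    return odds / (odds + 1)


def simulate_allelic_data(
    annotation: SyntheticAnnotation,
    peaks: SyntheticPeaks,
    config: SimulationConfig | None = None,
) -> SyntheticAllelic:
    config = config or annotation.config
    rng = _stage_rng(config.seed, 2)

    gene_ids = sorted(g.gene_id for g in annotation.genes)
    n_expr = min(config.n_expressed_genes, len(gene_ids))
    expressed = sorted(
        np.array(gene_ids)[rng.choice(len(gene_ids), n_expr, replace=False)]
    )
    n_meg = round(config.meg_fraction * n_expr)
    n_peg = round(config.peg_fraction * n_expr)
    labels = (["MEG"] * n_meg + ["PEG"] * n_peg
              + ["biallelic"] * (n_expr - n_meg - n_peg))
    labels = list(np.array(labels)[rng.permutation(n_expr)])

    count_rows = []
    truth_rows = []
    dmin, dmax = config.depth_range
    for gene, label in zip(expressed, labels):
        for cross in (CROSS_2X, CROSS_3X):
            mu = planted_fraction(cross, label, config.imprinting_fold,
                                  config.label_margin)
            truth_rows.append({"gene_id": gene, "cross": cross, "label": label})
            for rep in range(1, config.n_replicates + 1):
                depth = int(rng.integers(dmin, dmax + 1))
                maternal = _betabinom(rng, depth, mu, config.allelic_dispersion)
                count_rows.append(
                    {"gene_id": gene, "cross": cross, "replicate": rep,
                     "maternal": maternal, "paternal": depth - maternal}
                )
    counts = pd.DataFrame(count_rows)
    gene_truth = pd.DataFrame(truth_rows)

    # H3K27me3 archetypes and CG methylation around shared peak centers
    n_sites = len(peaks.truth)
    n_c1 = round(config.cluster1_fraction * n_sites)
    archetype = np.array(["cluster2"] * n_sites, dtype=object)
    archetype[rng.choice(n_sites, n_c1, replace=False)] = "cluster1"
    site_truth = peaks.truth[["peak_id"]].copy()
    site_truth["archetype"] = archetype
    label_by_gene = dict(zip(gene_truth["gene_id"], gene_truth["label"]))
    site_truth["target_label"] = [
        label_by_gene.get(g, "not_expressed") for g in peaks.truth["target_gene"]
    ]

    n_bins = config.signal_window // config.signal_bin
    half_bins = n_bins // 2
    dep = config.center_depletion_bins
    flank_profile = np.full(n_bins, config.flank_amplitude)
    flank_profile[half_bins - dep // 2 : half_bins + (dep + 1) // 2] = 0.0
    flat_profile = np.full(n_bins, config.signal_baseline)

    channels = {
        "h3k27me3_maternal": [], "h3k27me3_paternal": [], "h3k27me3_total": [],
        "cg_meth_maternal": [], "cg_meth_paternal": [],
    }
    order = peaks.truth.sort_values(["chrom", "center"], kind="stable")
    last_end: dict[str, int] = {}
    for idx, row in order.iterrows():
        start0 = row["center"] - config.signal_window // 2
        if start0 < 0:
            continue
        arch = site_truth.loc[idx, "archetype"]
        mat = (flank_profile if arch == "cluster1" else flat_profile).copy()
        pat = flat_profile.copy()
        mat = mat + rng.normal(0, config.signal_noise_sd, n_bins)
        pat = pat + rng.normal(0, config.signal_noise_sd, n_bins)
        meth_m = np.clip(
            config.meth_baseline + rng.normal(0, config.meth_noise_sd, n_bins),
            0, 1)
        boost = (config.meth_meg_paternal_boost
                 if site_truth.loc[idx, "target_label"] == "MEG" else 0.0)
        meth_p = np.clip(
            config.meth_baseline + boost
            + rng.normal(0, config.meth_noise_sd, n_bins), 0, 1)
        for b in range(n_bins):
            bs = start0 + b * config.signal_bin
            be = bs + config.signal_bin
            if bs < last_end.get(row["chrom"], 0):
                continue  # earlier site already wrote this region
            last_end[row["chrom"]] = be
            channels["h3k27me3_maternal"].append((row["chrom"], bs, be, mat[b]))
            channels["h3k27me3_paternal"].append((row["chrom"], bs, be, pat[b]))
            channels["h3k27me3_total"].append(
                (row["chrom"], bs, be, mat[b] + pat[b]))
            channels["cg_meth_maternal"].append((row["chrom"], bs, be, meth_m[b]))
            channels["cg_meth_paternal"].append((row["chrom"], bs, be, meth_p[b]))
    tracks = {
        name: pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        for name, rows in channels.items()
    }
    return SyntheticAllelic(counts, gene_truth,
                            site_truth[["peak_id", "archetype", "target_label"]],
                            tracks)


# --- bundle ----------------------------------------------------------------

@dataclass
class SyntheticBundle:
    config: SimulationConfig
    annotation: SyntheticAnnotation
    peaks: SyntheticPeaks
    allelic: SyntheticAllelic


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    annotation = simulate_annotation(config)
    peaks = simulate_peaks(annotation, config)
    allelic = simulate_allelic_data(annotation, peaks, config)
    return SyntheticBundle(config, annotation, peaks, allelic)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write the full dataset and truth tables; returns name -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    sio.write_fasta(bundle.annotation.genome, p("genome.fa"))
    genes = bundle.annotation.genes
    sio.write_gff3(
        IntervalSet(g.body for g in genes), p("genes.gff3"),
        feature_type="gene",
    )
    te = bundle.annotation.te_table
    with open(p("tes.bed"), "w") as fh:
        for r in te.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.te_id}\t0\t.\t"
                     f"{r.superfamily}\t{r.family}\n")
    sio.write_tsv(te, p("te_truth.tsv"))
    sio.write_bed(bundle.peaks.rep1, p("peaks_rep1.bed"))
    sio.write_bed(bundle.peaks.rep2, p("peaks_rep2.bed"))
    sio.write_tsv(bundle.peaks.truth, p("peak_truth.tsv"))
    sio.write_tsv(bundle.allelic.counts, p("allele_counts.tsv"))
    sio.write_tsv(bundle.allelic.gene_truth, p("gene_truth.tsv"))
    sio.write_tsv(bundle.allelic.site_truth, p("site_truth.tsv"))
    for name, df in bundle.allelic.tracks.items():
        sio.write_bedgraph(df, p(f"{name}.bedgraph"))
    bundle.config.to_yaml(p("config.yaml"))
    return paths
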