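"""Replicate-supported binding sites, TSS annotation and target-gene calls.

A binding site is the intersection of a peak from each of two ChIP
replicates (overlapping intersections merged). Sites are annotated to the
nearest transcription start site by signed, orientation-aware distance from
the site midpoint, and target genes are called with an inclusive window
(default 1.5 kb upstream to 0.5 kb downstream of the TSS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GeneModel, IntervalSet, intersect, overlap_fraction


@dataclass
class BindingSiteSet:
    """Common peak regions plus per-replicate reproducibility fractions."""

    sites: IntervalSet
    provenance: pd.DataFrame  # site_name, rep1_peak, rep2_peak
    reproducibility: dict[str, float]  # replicate -> fraction overlapping other

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class PeakAnnotation:
    site: GenomicInterval
    gene_id: str
    distance: int  # signed, negative = upstream of the TSS in gene orientation
    feature: str  # promoter | gene body | intergenic


def common_peaks(rep1: IntervalSet, rep2: IntervalSet) -> BindingSiteSet:
    """Binding sites supported by both replicates.

    Every overlapping rep1 x rep2 pair contributes its intersection interval;
    overlapping intersections are merged. Reproducibility per replicate is
    the fraction of its peaks overlapping at least one peak of the other.
    """
    if len(rep1) == 0 or len(rep2) == 0:
        raise ValueError("both replicate peak sets must be non-empty")
    pairs = intersect(rep1, rep2)
    raw = []
    prov = []
    for a, b, _ in pairs:
        start, end = max(a.start, b.start), min(a.end, b.end)
        raw.append(GenomicInterval(a.chrom, start, end))
        prov.append((a.chrom, start, end, a.name, b.name))
    sites = IntervalSet(raw).merged()
    named = IntervalSet(
        GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"site_{i:05d}")
        for i, iv in enumerate(sites)
    )
    # attach each contributing pair to the merged site containing it
    prov_rows = []
    for chrom, start, end, n1, n2 in prov:
        for site in named.by_chrom(chrom):
            if site.start <= start and end <= site.end:
                prov_rows.append(
                    {"site": site.name, "rep1_peak": n1, "rep2_peak": n2}
                )
                break
    reproducibility = {
        "rep1": overlap_fraction(rep1, rep2),
        "rep2": overlap_fraction(rep2, rep1),
    }
    return BindingSiteSet(named, pd.DataFrame(prov_rows), reproducibility)


def annotate_sites(
    sites: BindingSiteSet | IntervalSet,
    genes: list[GeneModel],
    promoter_span: int = 3000,
) -> list[PeakAnnotation]:
    """Annotate each site to its nearest TSS and a genomic feature class.

    The signed distance runs from the site midpoint to the nearest TSS in the
    orientation of that gene (negative = upstream). Feature class: promoter
    when the midpoint lies within ``promoter_span`` upstream of the TSS, gene
    body when it falls inside the nearest gene's span, intergenic otherwise.
    """
    if not genes:
        raise ValueError("at least one gene model is required")
    site_set = sites.sites if isinstance(sites, BindingSiteSet) else sites
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    ann = []
    for chrom in site_set.chroms:
        cands = genes_by_chrom.get(chrom, [])
        if not cands:
            continue
        tss = np.array([g.tss for g in cands], dtype=np.int64)
        sign = np.array([1 if g.strand == "+" else -1 for g in cands])
        for site in site_set.by_chrom(chrom):
            signed = (site.midpoint - tss) * sign
            best = int(np.argmin(np.abs(signed)))
            gene = cands[best]
            distance = int(signed[best])
            if -promoter_span <= distance < 0:
                feature = "promoter"
            elif gene.body.start <= site.midpoint < gene.body.end:
                feature = "gene body"
            else:
                feature = "intergenic"
            ann.append(PeakAnnotation(site, gene.gene_id, distance, feature))
    return ann


def call_targets(
    annotations: list[PeakAnnotation],
    upstream: int = 1500,
    downstream: int = 500,
) -> set[str]:
    """Genes with a site midpoint within [-upstream, +downstream] of the TSS."""
    if upstream < 0 or downstream < 0:
        raise ValueError("window bounds must be non-negative")
    return {
        a.gene_id
        for a in annotations
        if -upstream <= a.distance <= downstream
    }


def annotation_table(annotations: list[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [a.site.name for a in annotations],
            "chrom": [a.site.chrom for a in annotations],
            "start": [a.site.start for a in annotations],
            "end": [a.site.end for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "distance_to_tss": [a.distance for a in annotations],
            "feature": [a.feature for a in annotations],
        }
    )
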