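"""Genomic-context battery for called MiDAS sites.

Covers the comparisons that distinguish the two MiDAS regimes: overlap between
site sets from different conditions, replication-timing assignment, genic
classification within a +/-50 kb window of the peak, gene-size and gene-density
statistics, distance to the nearest replication origin, overlap with the genes
of cytogenetically defined common fragile sites, and sampling of matched
control regions (early-replicating, R-loop-prone, away from MiDAS peaks).

All window operations are anchored at the bp midpoint of a site's
maximal-sigma peak bin and use half-open [anchor - w, anchor + w) windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfeasibleSamplingError, ValidationError
from .genome import GenomeLayout, GenomicInterval, IntervalSet
from .signal import MidasSite

RT_LABELS = ("early", "mid", "late", "undefined")


@dataclass
class ControlRegionSet:
    """One random control set: bin-wide regions passing all three constraints."""

    set_index: int
    regions: list[GenomicInterval]
    seed: int
    table: pd.DataFrame  # per region: rloop_count, gene_count in the +/-window


def overlap_site_sets(
    a: list[MidasSite], b: list[MidasSite], window: int = 600_000
) -> dict:
    """Directional anchor-distance matching between two site sets.

    A site in ``a`` is matched when some site of ``b`` on the same chromosome
    has an anchor within ``window`` bp; symmetric count reported for ``b``.
    ``pairs`` lists every matched (index-in-a, index-in-b) pair.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    b_anchors: dict[str, np.ndarray] = {}
    b_index: dict[str, np.ndarray] = {}
    for j, s in enumerate(b):
        b_anchors.setdefault(s.chrom, [])
        b_anchors[s.chrom].append((s.anchor, j))
    for chrom, lst in b_anchors.items():
        lst.sort()
        b_index[chrom] = np.array([j for _, j in lst], int)
        b_anchors[chrom] = np.array([x for x, _ in lst], int)
    pairs = []
    for i, s in enumerate(a):
        if s.chrom not in b_index:
            continue
        anchors = b_anchors[s.chrom]
        lo = np.searchsorted(anchors, s.anchor - window, side="left")
        hi = np.searchsorted(anchors, s.anchor + window, side="right")
        for j in b_index[s.chrom][lo:hi]:
            pairs.append((i, int(j)))
    return {
        "n_a_matched": len({i for i, _ in pairs}),
        "n_b_matched": len({j for _, j in pairs}),
        "pairs": pairs,
    }


def _validate_domains(domains: IntervalSet) -> None:
    for chrom in domains.chroms():
        starts, ends, _ = domains.by_chrom(chrom)
        order = np.argsort(starts)
        if np.any(ends[order][:-1] > starts[order][1:]):
            raise ValidationError(f"overlapping replication-timing domains on {chrom}")


def assign_replication_timing(
    sites: list[MidasSite], domains: IntervalSet
) -> list[str]:
    """Timing label of the domain containing each site anchor ('undefined' if none).

    Domain labels live in the interval ``label`` field and must be one of
    early/mid/late/undefined; domains may not overlap.
    """
    for iv in domains:
        if iv.label not in RT_LABELS:
            raise ValidationError(f"bad replication-timing label {iv.label!r}")
    _validate_domains(domains)
    labels = []
    for s in sites:
        hits = domains.overlapping(s.chrom, s.anchor, s.anchor + 1)
        labels.append(hits[0].label if hits else "undefined")
    return labels


def classify_genic(
    sites: list[MidasSite], genes: IntervalSet, window: int = 50_000
) -> pd.DataFrame:
    """Genic/intergenic call per site: genic iff >= 1 gene intersects the window."""
    rows = []
    for s in sites:
        hits = genes.overlapping(s.chrom, s.anchor - window, s.anchor + window)
        rows.append(
            {
                "site_id": s.site_id,
                "genic": "genic" if hits else "intergenic",
                "gene_count_window": len(hits),
                "genes_within_window": ",".join(iv.label for iv in hits),
            }
        )
    return pd.DataFrame(
        rows, columns=["site_id", "genic", "gene_count_window", "genes_within_window"]
    )


def gene_density(
    sites: list[MidasSite], genes: IntervalSet, window: int = 50_000
) -> dict:
    """Per-site gene counts in the +/-window plus a histogram summary."""
    counts = np.array(
        [genes.count_overlapping(s.chrom, s.anchor - window, s.anchor + window) for s in sites],
        int,
    )
    hist = np.bincount(counts) if len(counts) else np.array([], int)
    return {
        "counts": counts,
        "mean": float(counts.mean()) if len(counts) else float("nan"),
        "median": float(np.median(counts)) if len(counts) else float("nan"),
        "histogram": hist,
    }


def nearest_origin_distance(
    sites: list[MidasSite],
    origins: IntervalSet,
    bin_size: int = 10_000,
    max_distance: int | None = None,
) -> list[int | None]:
    """Edge-to-edge bp distance from each anchor bin to the nearest origin.

    The anchor bin is the ``bin_size``-aligned bin containing the anchor.
    Distance is 0 when bin and origin intersect; None ("unassigned") when the
    chromosome carries no origin or the minimum exceeds ``max_distance``.
    """
    out: list[int | None] = []
    for s in sites:
        starts, ends, _ = origins.by_chrom(s.chrom)
        if len(starts) == 0:
            out.append(None)
            continue
        a_start = (s.anchor // bin_size) * bin_size
        a_end = a_start + bin_size
        gaps = np.maximum(starts - a_end, 0) + np.maximum(a_start - ends, 0)
        d = int(gaps.min())
        out.append(None if (max_distance is not None and d > max_distance) else d)
    return out


def cfs_gene_overlap(site_genes, cfs_genes) -> dict:
    """Fraction of genes within MiDAS windows that are common-fragile-site genes.

    Labels are matched case-insensitively after whitespace stripping; the
    denominator is the number of distinct site genes.
    """
    norm = lambda g: str(g).strip().lower()
    site_set = {norm(g) for g in site_genes if str(g).strip()}
    if not site_set:
        raise ValidationError("empty site gene list")
    cfs_set = {norm(g) for g in cfs_genes}
    n_hit = len(site_set & cfs_set)
    return {"n_hit": n_hit, "n_total": len(site_set), "fraction": n_hit / len(site_set)}


def summarize_gene_sizes(site_genes: IntervalSet, reference_genes: IntervalSet) -> dict:
    """Gene-length medians of the two sets and a two-tailed Mann-Whitney p-value."""
    a = np.array([len(iv) for iv in site_genes], float)
    b = np.array([len(iv) for iv in reference_genes], float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("gene sets must be non-empty")
    stat_p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue if (len(a) and len(b)) else float("nan")
    return {
        "median_site": float(np.median(a)),
        "median_ref": float(np.median(b)),
        "test_p": float(stat_p),
    }


def sample_control_regions(
    rt_domains: IntervalSet,
    rloop_peaks: IntervalSet,
    midas_sites: list[MidasSite],
    genes: IntervalSet,
    layout: GenomeLayout,
    n: int = 150,
    n_sets: int = 10,
    exclusion_bins: int = 50,
    window: int = 50_000,
    seed: int = 0,
) -> list[ControlRegionSet]:
    """Sample matched control regions without replacement.

    Eligible bins have (i) their center inside an early replication-timing
    domain, (ii) no MiDAS peak bin within ``exclusion_bins`` bins, and (iii)
    >= 1 R-loop peak intersecting [center - window, center + window). Each of
    the ``n_sets`` sets draws ``n`` distinct bins with a seed derived from
    (seed, set index), so a single seed reproduces all sets.
    """
    early = IntervalSet([iv for iv in rt_domains if iv.label == "early"], "rt_domain")
    peak_bins: dict[str, set[int]] = {}
    for s in midas_sites:
        peak_bins.setdefault(s.chrom, set()).update(s.peak_bins)
    pool: list[tuple[str, int]] = []
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        excluded = np.zeros(nb, bool)
        for p in peak_bins.get(chrom, ()):
            excluded[max(0, p - exclusion_bins):min(nb, p + exclusion_bins + 1)] = True
        e_starts, e_ends, _ = early.by_chrom(chrom)
        for b in range(nb):
            if excluded[b]:
                continue
            center = layout.bin_mid(chrom, b)
            if not np.any((e_starts <= center) & (e_ends > center)):
                continue
            if rloop_peaks.count_overlapping(chrom, center - window, center + window) < 1:
                continue
            pool.append((chrom, b))
    if len(pool) < n:
        raise InfeasibleSamplingError(len(pool), n)
    sets = []
    for k in range(1, n_sets + 1):
        rng = np.random.default_rng([seed, k])
        pick = rng.choice(len(pool), size=n, replace=False)
        regions, rows = [], []
        for idx in sorted(pick):
            chrom, b = pool[idx]
            start = layout.bin_start(b)
            end = min(start + layout.bin_size, layout.length(chrom))
            center = layout.bin_mid(chrom, b)
            regions.append(GenomicInterval(chrom, start, end, ".", f"set{k}"))
            rows.append(
                {
                    "chrom": chrom,
                    "bin": b,
                    "rloop_count": rloop_peaks.count_overlapping(chrom, center - window, center + window),
                    "gene_count": genes.count_overlapping(chrom, center - window, center + window),
                }
            )
        sets.append(ControlRegionSet(k, regions, seed, pd.DataFrame(rows)))
    return sets


def annotate_sites(
    sites: list[MidasSite],
    rt_domains: IntervalSet | None = None,
    genes: IntervalSet | None = None,
    origins: IntervalSet | None = None,
    cfs_genes=None,
    gene_window: int = 50_000,
) -> pd.DataFrame:
    """One row per site combining timing, genic status, and origin distance."""
    if not sites:
        cols = ["site_id", "chrom", "anchor", "shape", "max_sigma", "timing",
                "genic", "gene_count_window", "genes_within_window",
                "nearest_origin_distance", "cfs_gene_hit"]
        return pd.DataFrame(columns=cols)
    frame = pd.DataFrame({"site_id": [s.site_id for s in sites],
                          "chrom": [s.chrom for s in sites],
                          "anchor": [s.anchor for s in sites],
                          "shape": [s.shape for s in sites],
                          "max_sigma": [s.max_sigma for s in sites]})
    if rt_domains is not None:
        frame["timing"] = assign_replication_timing(sites, rt_domains)
    if genes is not None:
        frame = frame.merge(classify_genic(sites, genes, gene_window), on="site_id")
    if origins is not None:
        dists = nearest_origin_distance(sites, origins)
        frame["nearest_origin_distance"] = [d if d is not None else pd.NA for d in dists]
    if cfs_genes is not None and genes is not None:
        cfs_norm = {str(g).strip().lower() for g in cfs_genes}
        frame["cfs_gene_hit"] = [
            any(g.strip().lower() in cfs_norm for g in row.split(",") if g)
            for row in frame["genes_within_window"]
        ]
    return frame
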