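"""Synthetic genome generator with planted ground truth.

Builds a toy genome carrying every structure the analysis battery assumes:

* alternating early/mid/late replication-timing domains;
* two planted-site regimes: ``brca2_like`` sites sit in early domains inside
  average-size, highly transcribed, R-loop-forming genes next to an
  early-firing origin, while ``aph_like`` sites sit in late domains inside
  long genes, far from origins — the two contrasts the analyses are built to
  separate;
* replication origins confined to early domains, with one origin planted
  up- or downstream of each brca2_like host gene so the local fork direction
  realizes an intended co-directional or head-on conflict orientation;
* an analytic sawtooth RFD track (+1 just right of each origin, decreasing
  linearly to -1 just left of the next);
* log-normally expressed genes whose highly transcribed tier hosts R-loop
  peaks; G-quadruplexes clustered around R-loops over a uniform background;
* Poisson (optionally negative-binomial) background bin counts with
  Gaussian-shaped enrichments at planted sites, single or double peaked;
* two tumor cohorts whose breakpoints hit brca2_like site windows at
  different per-tumor rates, over uniform background rearrangements.

Everything is deterministic given (config, seed); independent components
draw from seeds derived as (seed, component) so e.g. regenerating the SV
catalog never perturbs the count track.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .genome import (
    BinTrack,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    write_bedgraph,
    write_intervals,
)
from .orientation import RFDTrack, SVCatalog, SVRecord, write_sv_table
from .signal import MidasSite
from .transcription import SignalTrack

# GRCh37 chromosome sizes, used by the synthetic stand-in site tables.
HG19_CHROM_SIZES = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic world.

    Defaults encode the regime the analyses target: ~50 reads per 10-kb bin of
    background, 20 planted sites at 8-fold enrichment on a 2 x 50-Mb genome,
    one fifth double-peaked, 80% of site host genes transcribed in early
    S-phase, and tumor cohorts of 469 wild-type / 39 mutated samples hitting
    site windows at 5% / 30% per tumor.
    """

    n_chroms: int = 2
    chrom_length: int = 50_000_000
    bin_size: int = 10_000
    background_lambda: float = 50.0
    n_planted_sites: int = 20
    enrichment_fold: float = 8.0
    double_peak_fraction: float = 0.2
    scenario: str = "brca2_like"        # brca2_like | aph_like | mixed
    gene_size_log_mean: float = math.log(40_000.0)
    gene_size_log_sd: float = 0.8
    rt_domain_length: int = 1_200_000
    rloop_fraction_of_transcribed_genes: float = 0.8
    transcribed_site_fraction: float = 0.8
    codirectional_fraction: float = 0.78
    n_decoy_rloop_genes: int = 40
    n_background_genes: int = 400
    g4_background_per_kb: float = 0.03
    g4_per_site_rloop: float = 18.0
    g4_per_decoy_rloop: float = 5.0
    sv_rate_near_sites: float = 0.30
    sv_rate_background: float = 0.05
    sv_background_per_tumor: float = 2.0
    n_tumors_wildtype: int = 469
    n_tumors_mutated: int = 39
    nb_dispersion: float | None = None  # negative-binomial overdispersion switch

    def __post_init__(self):
        if min(self.n_chroms, self.chrom_length, self.bin_size, self.rt_domain_length) <= 0:
            raise ValidationError("chromosome/bin/domain dimensions must be positive")
        if self.background_lambda <= 0 or self.enrichment_fold <= 0:
            raise ValidationError("rates must be positive")
        for f in (self.double_peak_fraction, self.rloop_fraction_of_transcribed_genes,
                  self.transcribed_site_fraction, self.codirectional_fraction,
                  self.sv_rate_near_sites, self.sv_rate_background):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("fractions must be in [0, 1]")
        if self.scenario not in ("brca2_like", "aph_like", "mixed"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")


@dataclass
class PlantedSite:
    site_id: str
    chrom: str
    anchor: int                 # bp position of the primary enrichment bump
    bump_positions: list[int]   # bp positions of all bumps (1 or 2)
    scenario: str               # brca2_like | aph_like
    shape: str                  # single | multiple
    gene_id: str
    gene_strand: str
    orientation: str            # intended conflict orientation (brca2_like only)
    transcribed: bool


@dataclass
class SyntheticTruth:
    config: SyntheticConfig
    layout: GenomeLayout
    sites: list[PlantedSite]
    genes: IntervalSet
    expression: pd.DataFrame    # gene_id, length_bp, level, count
    rt_domains: IntervalSet
    origins: IntervalSet
    rloop_peaks: IntervalSet
    g4_positions: IntervalSet
    rfd: RFDTrack
    eu_plus: SignalTrack
    eu_minus: SignalTrack


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), component])


def generate_world(config: SyntheticConfig, seed: int = 0) -> SyntheticTruth:
    """Build the full synthetic truth; deterministic given (config, seed)."""
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        tuple(config.chrom_length for _ in range(config.n_chroms)),
        config.bin_size,
    )
    rng = _rng(seed, 1)

    # --- replication-timing domains: tiled early/mid/late cycle -------------
    rt, early_domains, late_domains = [], [], []
    cycle = ("early", "mid", "late")
    for chrom in layout.chrom_names:
        pos, k = 0, 0
        while pos < config.chrom_length:
            end = min(pos + config.rt_domain_length, config.chrom_length)
            timing = cycle[k % 3]
            rt.append(GenomicInterval(chrom, pos, end, ".", timing))
            if timing == "early" and end - pos == config.rt_domain_length:
                early_domains.append((chrom, pos, end))
            if timing == "late" and end - pos == config.rt_domain_length:
                late_domains.append((chrom, pos, end))
            pos, k = end, k + 1
    rt_domains = IntervalSet(rt, "rt_domain")

    # --- planted sites ------------------------------------------------------
    n = config.n_planted_sites
    if config.scenario == "brca2_like":
        n_brca2, n_aph = n, 0
    elif config.scenario == "aph_like":
        n_brca2, n_aph = 0, n
    else:
        n_brca2 = n // 2
        n_aph = n - n_brca2
    if n_brca2 > len(early_domains) or n_aph > len(late_domains):
        raise GenerationError(
            f"cannot place {n_brca2} early + {n_aph} late sites in "
            f"{len(early_domains)} early / {len(late_domains)} late domains"
        )
    early_pick = [early_domains[i] for i in rng.permutation(len(early_domains))[:n_brca2]]
    late_pick = [late_domains[i] for i in rng.permutation(len(late_domains))[:n_aph]]

    n_double = round(config.double_peak_fraction * n)
    double_flags = np.zeros(n, bool)
    double_flags[rng.permutation(n)[:n_double]] = True
    n_transcribed = round(config.transcribed_site_fraction * n_brca2)
    transcribed_flags = np.zeros(n_brca2, bool)
    transcribed_flags[rng.permutation(n_brca2)[:n_transcribed]] = True

    bs = config.bin_size
    L = config.rt_domain_length
    sites: list[PlantedSite] = []
    genes: list[GenomicInterval] = []
    expr_rows: list[dict] = []
    origins: list[GenomicInterval] = []
    rloops: list[GenomicInterval] = []

    def add_gene(gene_id, chrom, start, end, strand, level):
        genes.append(GenomicInterval(chrom, start, end, strand, gene_id))
        expr_rows.append({"gene_id": gene_id, "length_bp": end - start, "level": level})

    for i, (chrom, dstart, dend) in enumerate(early_pick):
        sid = f"true_brca2_{i + 1:03d}"
        anchor_bin = int((dstart + rng.uniform(0.35, 0.65) * L) // bs)
        anchor = layout.bin_mid(chrom, anchor_bin)
        orientation = "co-directional" if rng.random() < config.codirectional_fraction else "head-on"
        strand = "+" if rng.random() < 0.5 else "-"
        # the origin sits transcriptionally upstream for co-directional sites
        # and downstream for head-on sites; which genomic side that is depends
        # on the gene strand
        origin_left = (strand == "+") == (orientation == "co-directional")
        bumps = [anchor]
        shape = "single"
        if double_flags[i]:
            # bumps close enough to merge into a single multiple-peak region,
            # planted on the side away from the origin so the gene can cover
            # both bumps while the origin stays within 100 kb of the anchor
            sep = int(rng.integers(4, 9))
            bump2_bin = anchor_bin + (sep if origin_left else -sep)
            bumps.append(layout.bin_mid(chrom, bump2_bin))
            shape = "multiple"
        glen = int(np.clip(rng.lognormal(math.log(4e4), 0.3), 25_000, 70_000))
        gstart = int(anchor - rng.uniform(0.3, 0.7) * glen)
        gend = gstart + glen
        # the host gene must stay within +/-50 kb of whichever bump becomes the
        # called anchor, so double-peak genes extend past the second bump
        gstart = min(gstart, min(bumps) - 25_000)
        gend = max(gend, max(bumps) + 25_000)
        transcribed = bool(transcribed_flags[i])
        level = float(rng.lognormal(math.log(50.0), 0.4)) if transcribed else 0.0
        add_gene(f"g_{sid}", chrom, gstart, gend, strand, level)
        offset = int(rng.uniform(20_000, 50_000))
        opos = gstart - offset if origin_left else gend + offset
        opos = int(np.clip(opos, dstart + 1_000, dend - 2_000))
        origins.append(GenomicInterval(chrom, opos, opos + 1_000, ".", f"ori_{sid}"))
        rpos = int(anchor + rng.uniform(-20_000, 20_000))
        rloops.append(GenomicInterval(chrom, rpos - 1_500, rpos + 1_500, ".", f"rloop_{sid}"))
        sites.append(PlantedSite(sid, chrom, anchor, bumps, "brca2_like", shape,
                                 f"g_{sid}", strand, orientation, transcribed))

    for i, (chrom, dstart, dend) in enumerate(late_pick):
        sid = f"true_aph_{i + 1:03d}"
        anchor_bin = int((dstart + rng.uniform(0.25, 0.35) * L) // bs)
        anchor = layout.bin_mid(chrom, anchor_bin)
        bumps = [anchor]
        shape = "single"
        if double_flags[n_brca2 + i]:
            max_sep = min(60, (dend - 100_000 - anchor) // bs)
            sep = int(rng.integers(20, max(21, max_sep + 1)))
            bumps.append(layout.bin_mid(chrom, anchor_bin + sep))
            shape = "multiple"
        gstart = int(bumps[0] - rng.uniform(30_000, 80_000))
        gend = int(bumps[-1] + rng.uniform(30_000, 80_000))
        if len(bumps) == 1:
            gend = gstart + int(rng.uniform(300_000, 700_000))
        gstart = max(gstart, dstart)
        gend = min(gend, dend)
        strand = "+" if rng.random() < 0.5 else "-"
        level = float(rng.lognormal(math.log(2.0), 0.5))
        add_gene(f"g_{sid}", chrom, gstart, gend, strand, level)
        sites.append(PlantedSite(sid, chrom, anchor, bumps, "aph_like", shape,
                                 f"g_{sid}", strand, "", False))

    # --- early-firing origins at domain edges -------------------------------
    for chrom, dstart, dend in early_domains:
        for opos in (dstart + 100_000, dend - 101_000):
            origins.append(GenomicInterval(chrom, opos, opos + 1_000, ".", "ori_edge"))

    # --- decoy transcribed R-loop genes (control-region pool) ---------------
    anchors_by_chrom: dict[str, list[int]] = {}
    for s in sites:
        anchors_by_chrom.setdefault(s.chrom, []).extend(s.bump_positions)
    placed: dict[str, list[int]] = {c: [] for c in layout.chrom_names}
    attempts, k = 0, 0
    while k < config.n_decoy_rloop_genes and attempts < 50 * max(config.n_decoy_rloop_genes, 1):
        attempts += 1
        chrom, dstart, dend = early_domains[int(rng.integers(len(early_domains)))]
        pos = int(rng.uniform(dstart + 120_000, dend - 120_000))
        if any(abs(pos - a) < 620_000 for a in anchors_by_chrom.get(chrom, [])):
            continue
        if any(abs(pos - p) < 120_000 for p in placed[chrom]):
            continue
        placed[chrom].append(pos)
        k += 1
        glen = int(np.clip(rng.lognormal(math.log(4e4), 0.4), 25_000, 90_000))
        gid = f"g_decoy_{k:03d}"
        level = float(rng.lognormal(math.log(15.0), 0.4))
        add_gene(gid, chrom, pos - glen // 2, pos - glen // 2 + glen, "+" if rng.random() < 0.5 else "-", level)
        rloops.append(GenomicInterval(chrom, pos - 1_500, pos + 1_500, ".", f"rloop_{gid}"))
    if k < config.n_decoy_rloop_genes:
        raise GenerationError(f"placed only {k} of {config.n_decoy_rloop_genes} decoy genes")

    # --- background genes (kept clear of site windows) ----------------------
    for j in range(config.n_background_genes):
        chrom = layout.chrom_names[int(rng.integers(config.n_chroms))]
        glen = int(np.clip(rng.lognormal(config.gene_size_log_mean, config.gene_size_log_sd),
                           5_000, 2_000_000))
        gstart = int(rng.integers(0, max(1, config.chrom_length - glen)))
        if any(gstart - 60_000 < a < gstart + glen + 60_000 for a in anchors_by_chrom.get(chrom, [])):
            continue
        level = float(rng.lognormal(math.log(3.0), 1.0))
        add_gene(f"g_bg_{j + 1:04d}", chrom, gstart, gstart + glen,
                 "+" if rng.random() < 0.5 else "-", level)

    # R-loops over the most transcribed background genes
    bg = [r for r in expr_rows if r["gene_id"].startswith("g_bg_")]
    if bg:
        levels = np.array([r["level"] for r in bg])
        q75 = np.quantile(levels, 0.75)
        lookup = {g.label: g for g in genes}
        for r in bg:
            if r["level"] >= q75 and rng.random() < config.rloop_fraction_of_transcribed_genes:
                g = lookup[r["gene_id"]]
                mid = g.midpoint()
                rloops.append(GenomicInterval(g.chrom, max(0, mid - 1_500), mid + 1_500, ".", f"rloop_{g.label}"))

    # --- G-quadruplexes ------------------------------------------------------
    g4s: list[GenomicInterval] = []
    for chrom in layout.chrom_names:
        n_bg_g4 = rng.poisson(config.g4_background_per_kb * config.chrom_length / 1000)
        for pos in np.sort(rng.integers(0, config.chrom_length - 30, n_bg_g4)):
            g4s.append(GenomicInterval(chrom, int(pos), int(pos) + 30, ".", "g4"))
    for iv in rloops:
        mean = config.g4_per_site_rloop if iv.label.startswith("rloop_true") else config.g4_per_decoy_rloop
        for _ in range(rng.poisson(mean)):
            pos = int(np.clip(iv.midpoint() + rng.integers(-20_000, 20_000), 0,
                              config.chrom_length - 31))
            g4s.append(GenomicInterval(iv.chrom, pos, pos + 30, ".", "g4"))

    # --- expression read counts ---------------------------------------------
    for r in expr_rows:
        r["count"] = int(rng.poisson(r["level"] * r["length_bp"] / 1000.0))
    expression = pd.DataFrame(expr_rows, columns=["gene_id", "length_bp", "level", "count"])

    # --- EU-seq-like stranded nascent-transcription signal ------------------
    eu = {"+": {c: np.zeros(layout.n_bins(c)) for c in layout.chrom_names},
          "-": {c: np.zeros(layout.n_bins(c)) for c in layout.chrom_names}}
    for g, r in zip(genes, expr_rows):
        if r["level"] <= 0:
            continue
        vec = eu[g.strand if g.strand in "+-" else "+"][g.chrom]
        b0, b1 = g.start // bs, (g.end - 1) // bs
        for b in range(b0, b1 + 1):
            lo, hi = max(g.start, b * bs), min(g.end, (b + 1) * bs)
            vec[b] += r["level"] * (hi - lo) / bs

    # --- analytic sawtooth RFD ----------------------------------------------
    rfd_values: dict[str, np.ndarray] = {}
    origin_set = IntervalSet(origins, "origin")
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        centers = np.array([layout.bin_mid(chrom, b) for b in range(nb)], float)
        o_starts, o_ends, _ = origin_set.by_chrom(chrom)
        if len(o_starts) == 0:
            rfd_values[chrom] = np.full(nb, np.nan)
            continue
        omid = np.sort((o_starts + o_ends) // 2).astype(float)
        vec = np.empty(nb)
        vec[centers < omid[0]] = -1.0
        vec[centers >= omid[-1]] = 1.0
        for o0, o1 in zip(omid[:-1], omid[1:]):
            sel = (centers >= o0) & (centers < o1)
            vec[sel] = 1.0 - 2.0 * (centers[sel] - o0) / (o1 - o0)
        rfd_values[chrom] = vec

    return SyntheticTruth(
        config=config,
        layout=layout,
        sites=sorted(sites, key=lambda s: (s.chrom, s.anchor)),
        genes=IntervalSet(genes, "gene"),
        expression=expression,
        rt_domains=rt_domains,
        origins=origin_set,
        rloop_peaks=IntervalSet(rloops, "rloop"),
        g4_positions=IntervalSet(g4s, "g4"),
        rfd=RFDTrack(layout, rfd_values),
        eu_plus=SignalTrack(layout, eu["+"], "+"),
        eu_minus=SignalTrack(layout, eu["-"], "-"),
    )


def simulate_bin_counts(truth: SyntheticTruth, config: SyntheticConfig, seed: int = 0) -> BinTrack:
    """Poisson background plus Gaussian-shaped enrichments at planted bumps.

    Each bump raises the expected count of its center bin to
    ``enrichment_fold x background_lambda``, decaying over ~3 bins
    (Gaussian with 1-bin standard deviation). With ``nb_dispersion`` set, the
    background is negative-binomial via a gamma-Poisson mixture.
    """
    rng = _rng(seed, 11)
    layout = truth.layout
    lam = config.background_lambda
    values: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        mu = np.full(nb, lam)
        if config.nb_dispersion:
            shape = 1.0 / config.nb_dispersion
            mu = mu * rng.gamma(shape, 1.0 / shape, nb)
        values[chrom] = rng.poisson(mu).astype(np.int64)
    amp = (config.enrichment_fold - 1.0) * lam
    if amp > 0:
        for s in truth.sites:
            vec = values[s.chrom]
            for bump in s.bump_positions:
                c = bump // layout.bin_size
                for off in range(-5, 6):
                    b = c + off
                    if 0 <= b < len(vec):
                        vec[b] += rng.poisson(amp * math.exp(-0.5 * off * off))
    return BinTrack(layout, values, "raw_count")


def simulate_sv_catalog(truth: SyntheticTruth, config: SyntheticConfig, seed: int = 0) -> SVCatalog:
    """Two tumor cohorts with window-targeted and background rearrangements.

    Every brca2_like site window (+/-200 kb) receives a short deletion with
    per-tumor probability ``sv_rate_near_sites`` (mutated cohort) or
    ``sv_rate_background`` (wild-type); both cohorts also draw
    Poisson(``sv_background_per_tumor``) inter-chromosomal events uniformly.
    """
    rng = _rng(seed, 13)
    layout = truth.layout
    brca2_sites = [s for s in truth.sites if s.scenario == "brca2_like"]
    cohorts: dict[str, str] = {}
    records: list[SVRecord] = []
    plans = [("BRCA2-wild-type", "wt", config.n_tumors_wildtype, config.sv_rate_background),
             ("BRCA2-mutated", "mut", config.n_tumors_mutated, config.sv_rate_near_sites)]
    for cohort, prefix, n_tumors, rate in plans:
        for t in range(n_tumors):
            sample = f"{prefix}_{t + 1:04d}"
            cohorts[sample] = cohort
            for s in brca2_sites:
                if rng.random() >= rate:
                    continue
                length = layout.length(s.chrom)
                p1 = int(np.clip(s.anchor - 200_000 + rng.integers(0, 400_000), 0, length - 2))
                p2 = int(min(p1 + rng.integers(5_000, 50_000), length - 1))
                records.append(SVRecord(sample, cohort, s.chrom, p1, s.chrom, p2, "DEL"))
            for _ in range(rng.poisson(config.sv_background_per_tumor)):
                c1 = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
                c2 = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
                records.append(SVRecord(
                    sample, cohort,
                    c1, int(rng.integers(0, layout.length(c1))),
                    c2, int(rng.integers(0, layout.length(c2))), "TRA",
                ))
    return SVCatalog(records, cohorts)


def write_world(truth: SyntheticTruth, counts: BinTrack, catalog: SVCatalog | None,
                outdir, seed: int | None = None) -> None:
    """Emit the world as the plain-text files the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.layout.to_tsv(outdir / "genome.tsv")
    write_bedgraph(counts, outdir / "counts.bedgraph")
    write_intervals(truth.genes, outdir / "genes.bed")
    write_intervals(truth.rt_domains, outdir / "rt_domains.bed")
    write_intervals(truth.origins, outdir / "origins.bed")
    write_intervals(truth.rloop_peaks, outdir / "rloops.bed")
    write_intervals(truth.g4_positions, outdir / "g4s.bed")
    write_bedgraph(BinTrack(truth.layout, truth.rfd.values, "rfd"), outdir / "rfd.bedgraph")
    write_bedgraph(BinTrack(truth.layout, truth.eu_plus.values, "signal"), outdir / "eu_plus.bedgraph")
    write_bedgraph(BinTrack(truth.layout, truth.eu_minus.values, "signal"), outdir / "eu_minus.bedgraph")
    truth.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    if catalog is not None:
        write_sv_table(catalog, outdir / "svs.tsv")
    payload = {
        "config": dataclasses.asdict(truth.config),
        "seed": seed,
        "sites": [dataclasses.asdict(s) for s in truth.sites],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def synthetic_site_table_pair(seed: int = 0, n_a: int = 150, n_b: int = 346,
                              n_common: int = 10, window: int = 600_000
                              ) -> tuple[list[MidasSite], list[MidasSite]]:
    """SYNTHETIC stand-in for the two deposited condition-specific site tables.

    Constructs two site lists on hg19-sized chromosomes with a planted
    ground truth: exactly ``n_common`` of the ``n_a`` first-condition sites
    have a second-condition partner within ``window`` bp, and every other
    cross-set anchor pair is farther apart than ``window``. The lists mimic
    the deposited tables' shape (condition labels, sigma scores, single-bin
    regions) but the coordinates are synthetic.
    """
    if n_common > min(n_a, n_b):
        raise ValidationError("n_common cannot exceed either set size")
    rng = _rng(seed, 29)
    spacing = 2 * window + 200_000
    slots = []
    for chrom, length in HG19_CHROM_SIZES.items():
        pos = 1_000_000
        while pos < length - 1_000_000:
            slots.append((chrom, pos))
            pos += spacing
    need = n_a + (n_b - n_common)
    if need > len(slots):
        raise GenerationError(f"{need} slots needed, only {len(slots)} available")
    pick = rng.permutation(len(slots))[:need]

    def make(chrom, anchor_bp, cond, idx):
        b = anchor_bp // 10_000
        return MidasSite(
            chrom=chrom, region_start=b * 10_000, region_end=(b + 1) * 10_000,
            peak_bins=[int(b)], anchor=b * 10_000 + 5_000,
            max_sigma=float(3.5 + rng.random() * 25), shape="single",
            condition=cond, site_id=f"{cond}_{idx:04d}",
        )

    a_sites = [make(*slots[pick[i]], "-BRCA2", i + 1) for i in range(n_a)]
    b_sites = [make(*slots[pick[n_a + j]], "+BRCA2+APH", j + 1) for j in range(n_b - n_common)]
    partners = rng.permutation(n_a)[:n_common]
    for k, i in enumerate(sorted(partners)):
        a = a_sites[i]
        offset = int(rng.integers(150_000, window - 60_000))
        b_sites.append(make(a.chrom, a.anchor + offset, "+BRCA2+APH", n_b - n_common + k + 1))
    return a_sites, b_sites
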