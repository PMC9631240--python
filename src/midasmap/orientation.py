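"""Replication-fork directionality at MiDAS sites and tumor SV enrichment.

RFD is the per-bin Okazaki-fragment strand bias in [-1, 1]; positive values
mean predominantly rightward-moving forks. A transcription-replication
conflict at a single-gene site is co-directional when the fork direction
matches the gene's transcription direction (+ strand -> positive RFD) and
head-on when they oppose; |mean RFD| below a small threshold is ambiguous.

Structural variants are per-tumor breakpoint records grouped into cohorts;
per-site SV frequency is the percentage of tumors in a cohort with at least
one breakpoint (either end of any record) within a window of the site anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import NoDataError, ParseError, ValidationError
from .genome import GenomeLayout, GenomicInterval, IntervalSet
from .signal import MidasSite


@dataclass
class RFDTrack:
    """Per-bin replication fork directionality; missing bins are NaN."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, vec in self.values.items():
            if len(vec) != self.layout.n_bins(chrom):
                raise ValidationError(f"{chrom}: bin count mismatch")
            finite = vec[np.isfinite(vec)]
            if np.any(np.abs(finite) > 1 + 1e-9):
                raise ValidationError(f"{chrom}: |RFD| > 1")

    def negated(self) -> "RFDTrack":
        return RFDTrack(self.layout, {c: -v for c, v in self.values.items()})


@dataclass
class OrientationCall:
    site_id: str
    gene_strand: str
    mean_rfd: float
    call: str  # co-directional | head-on | ambiguous


@dataclass(frozen=True)
class SVRecord:
    sample_id: str
    cohort: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str = ""


@dataclass
class SVCatalog:
    """Breakpoint records plus the registered per-cohort sample lists.

    Cohort denominators come from the registered samples, not from the
    records, so tumors without any rearrangement still count in percentages.
    """

    records: list[SVRecord]
    cohorts: dict[str, str]  # sample_id -> cohort label

    def __post_init__(self):
        for r in self.records:
            if r.sample_id not in self.cohorts:
                raise ValidationError(f"sample {r.sample_id!r} not registered in a cohort")

    @property
    def samples_per_cohort(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cohort in self.cohorts.values():
            out[cohort] = out.get(cohort, 0) + 1
        return out

    def cohort_names(self) -> list[str]:
        return sorted(set(self.cohorts.values()))


def mean_rfd_over_site(
    site: MidasSite,
    rfd: RFDTrack,
    extent: str = "fixed_window",
    window: int = 150_000,
    gene: GenomicInterval | None = None,
) -> float:
    """Unweighted mean of non-missing RFD bins over the chosen extent.

    ``fixed_window`` (default) uses a window centered on the anchor;
    ``gene_body`` averages over the supplied gene's interval.
    """
    if extent not in ("fixed_window", "gene_body"):
        raise ValidationError(f"unknown extent {extent!r}")
    if extent == "gene_body":
        if gene is None:
            raise ValidationError("extent='gene_body' needs a gene interval")
        lo_bp, hi_bp = gene.start, gene.end
    else:
        lo_bp, hi_bp = site.anchor - window // 2, site.anchor + window // 2
    if site.chrom not in rfd.values:
        raise NoDataError(f"no RFD data on {site.chrom}")
    bs = rfd.layout.bin_size
    vec = rfd.values[site.chrom]
    lo = max(0, lo_bp // bs)
    hi = min(len(vec), -(hi_bp // -bs))
    seg = vec[lo:hi]
    seg = seg[np.isfinite(seg)]
    if len(seg) == 0:
        raise NoDataError(f"all RFD bins missing over {site.chrom}:{lo_bp}-{hi_bp}")
    return float(seg.mean())


def classify_orientation(
    site: MidasSite,
    gene_strand: str,
    mean_rfd: float,
    tau: float = 0.1,
) -> OrientationCall:
    """Co-directional / head-on / ambiguous call for a single-gene site."""
    if gene_strand not in ("+", "-"):
        raise ValidationError(f"gene strand must be +/- (got {gene_strand!r})")
    if abs(mean_rfd) < tau:
        call = "ambiguous"
    else:
        fork_sign = 1 if mean_rfd > 0 else -1
        gene_sign = 1 if gene_strand == "+" else -1
        call = "co-directional" if fork_sign == gene_sign else "head-on"
    return OrientationCall(site.site_id, gene_strand, float(mean_rfd), call)


def classify_sites_orientation(
    sites: list[MidasSite],
    genes: IntervalSet,
    rfd: RFDTrack,
    gene_window: int = 50_000,
    rfd_window: int = 150_000,
    tau: float = 0.1,
    extent: str = "fixed_window",
) -> tuple[list[OrientationCall], int]:
    """Orient every single-gene site; multi-gene/intergenic sites are skipped.

    Returns (calls, n_skipped). The restriction to sites whose +/-window holds
    exactly one gene makes the transcription direction unambiguous.
    """
    calls, skipped = [], 0
    for s in sites:
        hits = genes.overlapping(s.chrom, s.anchor - gene_window, s.anchor + gene_window)
        if len(hits) != 1 or hits[0].strand not in ("+", "-"):
            skipped += 1
            continue
        gene = hits[0]
        try:
            m = mean_rfd_over_site(s, rfd, extent=extent, window=rfd_window, gene=gene)
        except NoDataError:
            skipped += 1
            continue
        calls.append(classify_orientation(s, gene.strand, m, tau))
    return calls, skipped


def orientation_summary(calls: list[OrientationCall]) -> dict:
    if not calls:
        raise ValidationError("no orientation calls")
    n = len(calls)
    n_co = sum(c.call == "co-directional" for c in calls)
    n_ho = sum(c.call == "head-on" for c in calls)
    n_amb = n - n_co - n_ho
    return {
        "fraction_codirectional": n_co / n,
        "fraction_headon": n_ho / n,
        "fraction_ambiguous": n_amb / n,
        "n": n,
    }


def site_sv_frequency(
    sites: list[MidasSite], catalog: SVCatalog, window: int = 200_000
) -> pd.DataFrame:
    """Per site x cohort percentage of tumors with >= 1 breakpoint in the window.

    A tumor counts once per site if ANY end of ANY of its records lies in
    [anchor - w, anchor + w) on the site's chromosome; translocation records
    contribute both ends independently.
    """
    sizes = catalog.samples_per_cohort
    if any(v == 0 for v in sizes.values()) or not sizes:
        raise ValidationError("every cohort must have >= 1 registered sample")
    # flatten breakpoint ends per (cohort, chrom): sorted positions + sample ids
    ends: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for r in catalog.records:
        cohort = catalog.cohorts[r.sample_id]
        ends.setdefault((cohort, r.chrom1), []).append((r.pos1, r.sample_id))
        ends.setdefault((cohort, r.chrom2), []).append((r.pos2, r.sample_id))
    flat = {}
    for key, lst in ends.items():
        lst.sort()
        flat[key] = (np.array([p for p, _ in lst], int), [s for _, s in lst])
    rows = []
    for s in sites:
        row = {"site_id": s.site_id, "chrom": s.chrom, "anchor": s.anchor}
        for cohort, size in sizes.items():
            pos, samples = flat.get((cohort, s.chrom), (np.empty(0, int), []))
            lo = np.searchsorted(pos, s.anchor - window, side="left")
            hi = np.searchsorted(pos, s.anchor + window, side="left")
            hit_samples = {samples[i] for i in range(lo, hi)}
            row[f"pct_{cohort}"] = 100.0 * len(hit_samples) / size
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_sv_comparison(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA plus Tukey HSD across per-site percentage groups.

    ``groups`` maps a group label (cohort x site-set) to its vector of
    per-site percentages; every group needs >= 2 sites.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValidationError(f"group {k!r} has < 2 sites")
    anova = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    if np.ptp(values) == 0:
        tukey_rows = [
            {"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0}
            for i, a in enumerate(arrays) for b in list(arrays)[i + 1:]
        ]
    else:
        res = pairwise_tukeyhsd(values, labels)
        # results-table rows: (group1, group2, meandiff, p-adj, lower, upper, reject)
        tukey_rows = [
            {
                "group1": row[0],
                "group2": row[1],
                "meandiff": float(row[2]),
                "p_adj": float(p),
            }
            for row, p in zip(res._results_table.data[1:], res.pvalues)
        ]
    return {
        "group_means": {k: float(v.mean()) for k, v in arrays.items()},
        "group_medians": {k: float(np.median(v)) for k, v in arrays.items()},
        "anova_p": float(anova.pvalue),
        "tukey": tukey_rows,
    }


def read_sv_table(path, layout: GenomeLayout | None = None) -> SVCatalog:
    """Read the tab-separated SV table (sample_id, cohort, chrom1, pos1, chrom2, pos2, type).

    Every sample appearing in a record is registered to its cohort. Tumors
    without any rearrangement (they still belong in the percentage
    denominator) are declared with ``#cohort<TAB>sample<TAB>label`` lines.
    """
    records, cohorts = [], {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#cohort"):
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(path, lineno, "expected '#cohort<TAB>sample<TAB>label'")
                cohorts[parts[1]] = parts[2]
                continue
            if line.startswith("#") or line.startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(path, lineno, f"SV table needs 7 columns, got {len(parts)}")
            try:
                rec = SVRecord(parts[0], parts[1], parts[2], int(parts[3]), parts[4], int(parts[5]), parts[6])
            except ValueError:
                raise ParseError(path, lineno, "bad breakpoint coordinates") from None
            if parts[0] in cohorts and cohorts[parts[0]] != parts[1]:
                raise ParseError(path, lineno, f"sample {parts[0]!r} in two cohorts")
            cohorts[parts[0]] = parts[1]
            records.append(rec)
    return SVCatalog(records, cohorts)


def write_sv_table(catalog: SVCatalog, path) -> None:
    with_records = {r.sample_id for r in catalog.records}
    with open(path, "w") as fh:
        fh.write("sample_id\tcohort\tchrom1\tpos1\tchrom2\tpos2\ttype\n")
        for sample, cohort in catalog.cohorts.items():
            if sample not in with_records:
                fh.write(f"#cohort\t{sample}\t{cohort}\n")
        for r in catalog.records:
            fh.write(
                f"{r.sample_id}\t{r.cohort}\t{r.chrom1}\t{r.pos1}\t{r.chrom2}\t{r.pos2}\t{r.sv_type}\n"
            )
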