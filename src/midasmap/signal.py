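"""Sigma normalization of binned nascent-DNA counts and MiDAS site calling.

The enrichment statistic is a per-bin standard score of library-normalized
counts: with ``n_i = c_i / mean(c)`` (library-size normalization to mean 1),

    sigma_i = (n_i - center) / SD

where the spread SD is either the sample standard deviation of ``n`` over all
bins (``estimator="plain"``, center = mean) or the Gaussian-consistent MAD,
``1.4826 * median(|n - median(n)|)``, over nonzero bins (``estimator="robust"``,
center = median of nonzero bins; the default, so that enriched bins do not
inflate the denominator). ``center=False`` divides without centering, the
literal normalized-count-over-SD ratio. Sigma is invariant under uniform
scaling of the counts either way.

Site calling scans for contiguous runs of bins at or above a sigma threshold,
merges runs separated by short sub-threshold gaps, and reports the local
maxima inside each merged region; regions with two or more maxima are the
"multiple"-peak sites seen where forks stall at both edges of an
under-replicated region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateVarianceError, ParseError, ValidationError
from .genome import BinTrack, GenomeLayout


@dataclass
class SigmaTrack:
    layout: GenomeLayout
    sigma: dict[str, np.ndarray]
    normalization_meta: dict

    def concat(self) -> np.ndarray:
        return np.concatenate([self.sigma[c] for c in self.layout.chrom_names if c in self.sigma])


@dataclass
class MidasSite:
    """A called MiDAS site: bin-aligned region, its peak bins and shape."""

    chrom: str
    region_start: int
    region_end: int
    peak_bins: list[int]
    anchor: int            # bp midpoint of the maximal-sigma peak bin
    max_sigma: float
    shape: str             # "single" | "multiple"
    condition: str = ""
    site_id: str = ""

    def __post_init__(self):
        if self.shape not in ("single", "multiple"):
            raise ValidationError(f"bad shape {self.shape!r}")
        if (len(self.peak_bins) >= 2) != (self.shape == "multiple"):
            raise ValidationError("shape must be 'multiple' iff >= 2 peak bins")


def compute_sigma(
    counts: BinTrack,
    estimator: str = "robust",
    center: bool = True,
    estimation_chroms: tuple[str, ...] | None = None,
) -> SigmaTrack:
    """Normalize a raw-count track to per-bin sigma values.

    ``estimation_chroms`` restricts the bins entering the mean/SD estimate
    (e.g. autosomes only) while sigma is still emitted for every chromosome.
    """
    if estimator not in ("plain", "robust"):
        raise ValidationError(f"unknown estimator {estimator!r}")
    chroms = [c for c in counts.layout.chrom_names if c in counts.values]
    est_chroms = list(estimation_chroms) if estimation_chroms else chroms
    for c in est_chroms:
        if c not in counts.values:
            raise ValidationError(f"estimation chromosome {c!r} has no counts")
    est = np.concatenate([np.asarray(counts.values[c], float) for c in est_chroms])
    if np.count_nonzero(est) < 2:
        raise ValidationError("need at least 2 bins with nonzero counts")
    mean_count = est.mean()
    if mean_count == 0:
        raise ValidationError("all-zero count track")
    n_est = est / mean_count
    if estimator == "plain":
        loc = n_est.mean()
        sd = n_est.std(ddof=1)
    else:
        nz = n_est[n_est > 0]
        loc = float(np.median(nz))
        sd = 1.4826 * float(np.median(np.abs(nz - loc)))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateVarianceError(
            f"zero spread of normalized counts under the {estimator} estimator"
        )
    offset = loc if center else 0.0
    sigma = {
        c: (np.asarray(counts.values[c], float) / mean_count - offset) / sd
        for c in chroms
    }
    meta = {
        "mean_count": float(mean_count),
        "sd_estimate": float(sd),
        "estimator": estimator,
        "center": center,
        "location": float(loc),
    }
    return SigmaTrack(counts.layout, sigma, meta)


def _plateau_maxima(values: np.ndarray, lo: int, hi: int, threshold: float) -> list[int]:
    """Leftmost bins of strict local-maximum plateaus within [lo, hi].

    Neighbors are taken from the full vector (chromosome ends count as -inf);
    equal-value plateaus report their leftmost bin. Only bins at or above the
    threshold qualify.
    """
    peaks = []
    i = lo
    n = len(values)
    while i <= hi:
        v = values[i]
        j = i
        while j + 1 < n and values[j + 1] == v:
            j += 1
        left_lower = i == 0 or values[i - 1] < v
        right_lower = j == n - 1 or values[j + 1] < v
        if left_lower and right_lower and v >= threshold:
            peaks.append(i)
        i = j + 1
    return peaks


def call_midas_sites(
    sigma: SigmaTrack,
    threshold: float = 3.0,
    min_run: int = 2,
    merge_gap: int = 2,
    condition: str = "",
) -> list[MidasSite]:
    """Call MiDAS sites from a sigma track by local-maxima search.

    Contiguous runs of >= ``min_run`` bins with sigma >= ``threshold`` become
    candidate regions; candidates separated by <= ``merge_gap`` sub-threshold
    bins are merged. Local maxima inside each region become peak bins; the
    maximal-sigma peak bin's midpoint is the site anchor. Sites come back
    sorted by chromosome (layout order) then start.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if min_run < 1:
        raise ValidationError("min_run must be >= 1")
    if merge_gap < 0:
        raise ValidationError("merge_gap must be >= 0")
    if not sigma.sigma:
        raise ValidationError("empty sigma track")
    layout = sigma.layout
    sites: list[MidasSite] = []
    for chrom in layout.chrom_names:
        if chrom not in sigma.sigma:
            continue
        vec = sigma.sigma[chrom]
        above = vec >= threshold
        # contiguous runs of True, filtered by min_run
        runs = []
        i = 0
        while i < len(vec):
            if above[i]:
                j = i
                while j + 1 < len(vec) and above[j + 1]:
                    j += 1
                if j - i + 1 >= min_run:
                    runs.append([i, j])
                i = j + 1
            else:
                i += 1
        # merge runs separated by <= merge_gap sub-threshold bins (above-threshold
        # bins of runs shorter than min_run do not count against the gap)
        merged = []
        for run in runs:
            if merged and np.count_nonzero(~above[merged[-1][1] + 1:run[0]]) <= merge_gap:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        for lo, hi in merged:
            peaks = _plateau_maxima(vec, lo, hi, threshold)
            if not peaks:  # flat region at threshold: leftmost max wins
                peaks = [lo + int(np.argmax(vec[lo:hi + 1]))]
            best = peaks[int(np.argmax([vec[p] for p in peaks]))]
            sites.append(
                MidasSite(
                    chrom=chrom,
                    region_start=lo * layout.bin_size,
                    region_end=min((hi + 1) * layout.bin_size, layout.length(chrom)),
                    peak_bins=peaks,
                    anchor=layout.bin_mid(chrom, best),
                    max_sigma=float(vec[best]),
                    shape="multiple" if len(peaks) >= 2 else "single",
                    condition=condition,
                )
            )
    for k, site in enumerate(sites):
        if not site.site_id:
            site.site_id = f"{condition or 'midas'}_{k + 1:04d}"
    return sites


def sites_to_frame(sites: list[MidasSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "start": [s.region_start for s in sites],
            "end": [s.region_end for s in sites],
            "site_id": [s.site_id for s in sites],
            "max_sigma": [s.max_sigma for s in sites],
            "strand": ["." for _ in sites],
            "shape": [s.shape for s in sites],
            "condition": [s.condition for s in sites],
            "peak_bins": [",".join(map(str, s.peak_bins)) for s in sites],
            "anchor": [s.anchor for s in sites],
        }
    )


def write_sites(sites: list[MidasSite], path) -> None:
    """BED6+ site table: chrom, start, end, id, max_sigma, '.', shape, condition, peaks, anchor."""
    sites_to_frame(sites).to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def read_sites(path, layout: GenomeLayout | None = None) -> list[MidasSite]:
    sites = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(path, lineno, f"site table needs 10 columns, got {len(parts)}")
            try:
                peak_bins = [int(x) for x in parts[8].split(",") if x]
                sites.append(
                    MidasSite(
                        chrom=parts[0],
                        region_start=int(parts[1]),
                        region_end=int(parts[2]),
                        site_id=parts[3],
                        max_sigma=float(parts[4]),
                        shape=parts[6],
                        condition=parts[7],
                        peak_bins=peak_bins,
                        anchor=int(parts[9]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if layout is not None and parts[0] not in layout:
                raise ParseError(path, lineno, f"unknown chromosome {parts[0]!r}")
    return sites
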