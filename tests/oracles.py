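"""Independent brute-force oracles used to verify the vectorized paths.

Everything here is deliberately naive — plain Python loops and all-pairs
scans — and shares no code with the package implementation.
"""


def call_sites_oracle(vec, threshold=3.0, min_run=2, merge_gap=2):
    """Exhaustive scan site caller: [(lo_bin, hi_bin, (peak bins...)), ...]."""
    n = len(vec)
    above = [v >= threshold for v in vec]
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    regions = []
    for lo, hi in runs:
        if regions:
            plo, phi = regions[-1]
            gap = sum(1 for b in range(phi + 1, lo) if not above[b])
            if gap <= merge_gap:
                regions[-1] = (plo, hi)
                continue
        regions.append((lo, hi))
    out = []
    for lo, hi in regions:
        peaks = []
        i = lo
        while i <= hi:
            v = vec[i]
            j = i
            while j + 1 < n and vec[j + 1] == v:
                j += 1
            left_lower = i == 0 or vec[i - 1] < v
            right_lower = j == n - 1 or vec[j + 1] < v
            if left_lower and right_lower and v >= threshold:
                peaks.append(i)
            i = j + 1
        if not peaks:
            best = lo
            for b in range(lo, hi + 1):
                if vec[b] > vec[best]:
                    best = b
            peaks = [best]
        out.append((lo, hi, tuple(peaks)))
    return out


def intersects(iv, lo, hi):
    return iv.start < hi and iv.end > lo


def genes_in_window_oracle(site, genes, window):
    return [
        iv for iv in genes
        if iv.chrom == site.chrom and intersects(iv, site.anchor - window, site.anchor + window)
    ]


def nearest_origin_oracle(site, origins, bin_size=10_000):
    a_start = (site.anchor // bin_size) * bin_size
    a_end = a_start + bin_size
    best = None
    for iv in origins:
        if iv.chrom != site.chrom:
            continue
        if intersects(iv, a_start, a_end):
            d = 0
        elif iv.start >= a_end:
            d = iv.start - a_end
        else:
            d = a_start - iv.end
        if best is None or d < best:
            best = d
    return best


def overlap_pairs_oracle(a, b, window):
    pairs = []
    for i, sa in enumerate(a):
        for j, sb in enumerate(b):
            if sa.chrom == sb.chrom and abs(sa.anchor - sb.anchor) <= window:
                pairs.append((i, j))
    return pairs


def g4_density_oracle(site, g4s, span):
    half = span // 2
    lo, hi = site.anchor - half, site.anchor - half + span
    count = sum(1 for iv in g4s if iv.chrom == site.chrom and intersects(iv, lo, hi))
    return count / (span / 1000)


def sv_frequency_oracle(site, records, cohorts, window):
    """percentage per cohort of tumors with >= 1 breakpoint end in the window."""
    hits = {}
    for rec in records:
        for chrom, pos in ((rec.chrom1, rec.pos1), (rec.chrom2, rec.pos2)):
            if chrom == site.chrom and site.anchor - window <= pos < site.anchor + window:
                hits.setdefault(cohorts[rec.sample_id], set()).add(rec.sample_id)
    sizes = {}
    for cohort in cohorts.values():
        sizes[cohort] = sizes.get(cohort, 0) + 1
    return {c: 100.0 * len(hits.get(c, set())) / n for c, n in sizes.items()}


def profile_oracle(sites, values, bin_size, span):
    half = span // (2 * bin_size)
    rows = []
    for s in sites:
        c = s.anchor // bin_size
        vec = values[s.chrom]
        if c - half < 0 or c + half > len(vec):
            continue
        rows.append([vec[b] for b in range(c - half, c + half)])
    n = len(rows)
    return [sum(col) / n for col in zip(*rows)]
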