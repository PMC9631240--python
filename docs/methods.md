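# Methods

## Coordinate model and binning

All coordinates are 0-based half-open (BED convention); 1-based inputs must
be converted at the boundary. Bins are anchored at coordinate 0 of each
chromosome with a default width of 10 kb; the trailing partial bin is kept
and flagged. A read is represented by its alignment start and increments
bin ⌊pos/bin⌋; bedGraph record mass is split across overlapped bins in
proportion to overlap length. Chromosome names use the `chr` dialect; bare
names are mapped through an alias rule at load time. Alignment, duplicate
marking and mapping-quality filtering are upstream of this package — it
consumes positions or pre-binned counts.

## Sigma normalization

Counts are library-normalized to mean 1 (nᵢ = cᵢ/c̄, estimated over all
bins, optionally restricted to a chromosome subset) and converted to an
enrichment score in SD units, σᵢ = (nᵢ − μ)/ŝ. Two spread estimators are
offered:

- **plain** — μ = mean(n), ŝ = sample SD of n over all bins;
- **robust** (default) — μ = median, ŝ = 1.4826·MAD over nonzero bins, so
  that the enriched bins being searched for do not inflate the denominator.

Centering is on by default. A pure ratio nᵢ/ŝ (`center=False`) is also
offered, but for a dense background its baseline is c̄/ŝ ≈ √λ rather than
0, which makes a fixed σ threshold meaningless — at λ = 50 reads/bin the
uncentered baseline is ≈ 7, above any sensible calling threshold. A σ
threshold only expresses "this many SDs of enrichment" for the centered
score, which is why the centered form is the package's definition. σ is
invariant under uniform count scaling in either form. Degenerate spread
(constant counts, or a zero MAD when most nonzero bins are equal) raises an
error rather than returning infinities; the robust estimator needs count
diversity and the plain estimator is the fallback for tiny fixtures.

## Site calling

Candidate regions are contiguous runs of ≥ `min_run` (default 2) bins with
σ ≥ `threshold` (default 3.0); regions separated by ≤ `merge_gap`
(default 2) sub-threshold bins are merged (above-threshold bins of runs
shorter than `min_run` do not count against the gap). Within a region,
local maxima are equal-value plateaus strictly above both neighbors
(chromosome ends count as −∞), reported at their leftmost bin; a flat
region falls back to its leftmost maximal bin. A region with ≥ 2 maxima is
a "multiple"-peak site. The **anchor** — the bp midpoint of the maximal-σ
peak bin, ties leftmost — is the reference point for every window
operation downstream. Manual validation of peaks is replaced by these
deterministic filters; the threshold triple is exposed in the pipeline
config.

Note one non-obvious property: raising the threshold can *increase* the
number of called sites (a merged region can split into two runs that each
still satisfy `min_run`). The guaranteed monotone property, verified by the
tests, is containment: every site called at a higher threshold lies within
a site called at a lower one.

## Window operations

- Genic classification: a site is genic iff ≥ 1 gene interval intersects
  [anchor − 50 kb, anchor + 50 kb); the same window feeds gene counts,
  gene-size comparisons (two-tailed Mann-Whitney) and R-loop coincidence.
- Cross-condition site overlap: anchors within ±600 kb on the same
  chromosome, reported directionally for both sets. Midpoint anchors (not
  region edges) were chosen as the single well-defined per-site reference;
  the window is configurable.
- Nearest origin: edge-to-edge distance between the anchor's bin and the
  nearest origin interval on the same chromosome; "unassigned" when the
  chromosome has no origin (or beyond an optional cap).
- G4 density: count of G4 intervals in a 110-kb half-open window divided by
  110, in G4/kb.
- TPM: rate per gene count/(length/1000) rescaled to sum to 10⁶; log₁₀(TPM+1)
  accompanies it; a zero total rate yields an all-zero table with a warning.
- Transcribed-site classification: either supra-background EU-seq signal
  (sum over ±50 kb on either strand, background level configurable,
  default 0) or overlap with EU peak intervals — both are implemented
  behind a `mode` switch because the two give the same answer on clean
  signal but differ on noisy data.
- RFD orientation: mean of non-missing RFD bins over a 150-kb window
  centered on the anchor (gene-body extent optional). Restricted to sites
  whose ±50-kb window holds exactly one stranded gene, so transcription
  direction is unambiguous. Co-directional iff sign(mean RFD) matches the
  strand and |mean RFD| ≥ τ (default 0.1); opposite sign ⇒ head-on;
  |mean RFD| < τ ⇒ ambiguous. The sign convention is positive = rightward
  forks; tracks with the opposite convention are handled by `flip_rfd`.
- SV frequency: a tumor counts once per site when any end of any of its
  records falls in [anchor − 200 kb, anchor + 200 kb) on the site's
  chromosome; percentages use registered cohort sizes as denominators, so
  rearrangement-free tumors still count. Cohort contrasts use one-way ANOVA
  with Tukey HSD.

Control regions are 10-kb bins whose center is inside an early
replication-timing domain, ≥ 50 bins from every called peak bin, and with
≥ 1 R-loop peak within ±50 kb; 10 sets of 150 are drawn without replacement
inside each set, each set from a seed derived as (seed, set index), so one
integer reproduces everything.

## Synthetic worlds

The generator emulates the structures the analyses assume, with planted
ground truth; defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 50 Mb, 10-kb bins | desk-scale but large enough for ~28 early domains |
| background λ | 50 reads/bin | Poisson; NB via `nb_dispersion` |
| planted sites | 20 at 8× enrichment | Gaussian bumps, SD 1 bin (~3-bin width) |
| double-peak fraction | 0.2 | two bumps per site |
| RT domains | 1.2-Mb early/mid/late tiling | bin-resolution labels |
| transcribed site fraction | 0.8 | early-S transcription of site host genes |
| co-directional fraction | 0.78 | of planted conflict orientations |
| gene sizes | log-normal, median 40 kb | long (0.3–0.8 Mb) genes for the late-replicating regime |
| tumor cohorts | 469 wild-type / 39 mutated | per-tumor site-window hit rates 0.05 / 0.30, plus Poisson(2) background translocations per tumor |

`brca2_like` sites are placed one per early domain (inside a host gene,
with an R-loop peak within ±50 kb of the anchor and an origin within
100 kb); `aph_like` sites go to late domains inside long genes, ≥ 0.5 Mb
from any origin. Double-peak separations differ by regime: 4–8 bins for
`brca2_like` (the bumps merge into one multiple-peak region at the default
calling parameters) and 20–60 bins for `aph_like` (a long under-replicated
region whose two edges are called separately). The second bump is planted
on the side away from the site's origin so the host gene can span both
bumps without breaking the 100-kb origin-proximity guarantee.

Origins sit at early-domain edges plus one per `brca2_like` site, placed
transcriptionally upstream (co-directional) or downstream (head-on) of the
host gene; RFD is derived analytically from origin placement as a sawtooth
(+1 just right of an origin, linear to −1 just left of the next) rather
than simulated from Okazaki fragments — sufficient to exercise the
orientation classifier's sign/threshold logic, not a model of fork
kinetics. Expression levels are log-normal; site host genes draw from a
high tier, decoy R-loop genes (which guarantee a control-sampling pool
≥ 150 bins) from a middle tier, background genes from a low wide tier, with
R-loop peaks over the top expression quartile. G4s cluster around R-loops
(more densely at site R-loops) over a uniform background. Planted SVs are
short deletions with both ends inside the ±200-kb site window, so the
per-tumor window-hit probability equals the configured rate exactly;
background rearrangements are inter-chromosomal with uniform ends.

Randomness is partitioned: world structure, count noise and the SV catalog
draw from seeds derived as (seed, component), so regenerating one component
never perturbs another.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: mappability/GC artifacts and masked-genome
gaps, copy-number variation in tumor counts, overdispersion beyond the NB
switch, realistic gene overlap/isoform structure, distance-decaying SV
breakpoint clustering, and OK-seq noise in RFD. Recovery rates measured
here are upper bounds for real libraries.

## Numerical and degenerate-input choices

Windows are half-open everywhere, so a feature starting exactly at a window
end is excluded. Profile aggregation drops (and counts) sites whose window
would be truncated by a chromosome end. Missing RFD bins are NaN and are
excluded from means, never zero-filled; an all-missing extent is an error.
Tukey HSD degenerates on zero-variance input, so identical-group
comparisons return p = 1 directly. Site tables round-trip through text at
six significant digits of σ. The bedGraph writer emits one line per bin
(zeros included) so re-parsing is exact.

## Synthetic stand-ins

`synthetic_site_table_pair` builds the two condition-labelled site tables
(150 and 346 sites on hg19-sized chromosomes) used by the cross-condition
overlap check. It is synthetic by construction: exactly 10 of the 150 have
a partner within ±600 kb and all other cross-set distances exceed the
window, giving the overlap operation a planted ground truth at realistic
genome scale.

## Known limitations

The caller assumes an approximately homogeneous background; strong regional
coverage trends would need a local background model. Orientation calls are
only made at single-gene sites, as multi-gene windows leave transcription
direction ambiguous. The per-site SV percentage treats tumors as
exchangeable and ignores per-tumor SV burden. Desk-scale problem sizes
(2 × 50 Mb, 10–20 replicate seeds) were chosen so the full suite and the
reproduction script each run in seconds while keeping ≥ 10⁴ background bins
per world for stable spread estimates.
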