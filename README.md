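# midasmap

Mapping and genomic-context analysis of **mitotic DNA synthesis (MiDAS)**
sites from nascent-DNA sequencing.

Cells that enter mitosis with under-replicated DNA finish replication during
early mitosis; sequencing EdU-labelled mitotic nascent DNA (MiDAS-seq) maps
where that repair synthesis happens. Two regimes matter: BRCA2-deficient
cells fire MiDAS at **early-replicating, gene-dense, highly transcribed,
R-loop-forming** loci next to early origins — the signature of
transcription–replication conflicts — while replication stress from low-dose
aphidicolin triggers MiDAS at **late-replicating, origin-poor** common
fragile sites inside very long genes. `midasmap` implements the full
analysis chain that separates the two, plus a synthetic-genome generator
with planted ground truth so every stage is testable without any download.

## The model

Reads are assigned to fixed 10-kb genomic bins. With per-bin counts
$c_i$, counts are library-normalized to mean 1, $n_i = c_i/\bar c$, and
expressed as a standard enrichment score in SD units,

$$\sigma_i = \frac{n_i - \mu_n}{\hat s_n},$$

where $(\mu_n, \hat s_n)$ is either the mean and sample standard deviation
of $n$ (plain estimator), or the median and Gaussian-consistent MAD,
$1.4826\,\mathrm{med}\,|n-\mathrm{med}(n)|$, over nonzero bins (robust,
default — enriched bins cannot inflate the denominator). $\sigma$ is
invariant under uniform count scaling, so calls don't depend on library
size. MiDAS sites are contiguous runs of $\ge$ 2 bins with
$\sigma \ge 3$, merged across $\le$ 2 sub-threshold bins; local maxima
within a region are its peaks (two or more ⇒ a "multiple"-peak site, forks
stalled at both edges of an under-replicated region), and the maximal-σ peak
bin's midpoint anchors every downstream window operation: genic status
(±50 kb), replication-timing label, nearest-origin distance, R-loop
coincidence (±50 kb), G4 density (110 kb span), TPM-based expression,
OK-seq replication-fork directionality (RFD, mean over 150 kb; positive =
rightward forks, so sign agreement with the gene strand means a
co-directional conflict), and per-tumor structural-variant frequency
(±200 kb).

## Worked example

`examples/01_simulate_and_call.py` plants 20 sites at 8-fold enrichment over
a Poisson background of 50 reads/bin on a 2 × 50 Mb genome and recovers
them:

```
planted sites : 20
called sites  : 20
shapes        : {'single': 16, 'multiple': 4}
max sigma     : 54.1
  -BRCA2_0001  chr1:4190000-4240000  sigma=40.7  shape=single
  ...
calls matching a planted bump: 20/20
```

Every call matches a planted enrichment — recall 20/20 with no false
positives at σ ≥ 3. The context battery
(`examples/02_annotate_context.py`–`04_orientation_and_svs.py`) then prints

```
replication timing of site anchors: {'early': 20}
genic sites: 100%
median distance to nearest origin: 62 kb
R-loop coincident sites: 18/20 (90%)
transcribed in early S-phase: 16/20 (80%)
G4 density: sites 0.186/kb vs controls 0.072/kb
co-directional 75%  head-on 25%  ambiguous 0%
tumors with a breakpoint within 200 kb of a site: mutated 29.4%  wild-type 6.1%
```

i.e. the called sites are early-replicating, genic, origin-proximal,
mostly R-loop-coincident and transcribed, G4-enriched versus matched
controls, predominantly co-directional with replication, and hit far more
often by rearrangements in the BRCA2-mutated tumor cohort (planted
per-tumor rates 0.30 vs 0.05 are recovered as 29.4% vs 6.1%; the wild-type
value carries ~1.5 points of uniform background rearrangements).

## Layout

- `src/midasmap/genome.py` — coordinate model, BED/bedGraph I/O, binning
- `src/midasmap/signal.py` — σ normalization, site calling
- `src/midasmap/annotate.py` — overlap, timing, genic, origins, controls
- `src/midasmap/transcription.py` — R-loops, profiles, G4, TPM, EU signal
- `src/midasmap/orientation.py` — RFD orientation calls, tumor SV frequency
- `src/midasmap/simulate.py` — synthetic worlds with planted truth
- `src/midasmap/pipeline.py`, `cli.py` — orchestration and the CLI
- `docs/methods.md` — models, parameters, numerical choices, limitations
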