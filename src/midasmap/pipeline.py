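"""End-to-end orchestration: sigma -> site calling -> context annotation ->
R-loop/transcription analytics -> orientation and SV enrichment.

The pipeline is a pure function of its inputs and configuration (the only
randomness, control-region sampling, is seeded), writes every stage product
as a tab-separated table or bedGraph under the output directory, and records
a manifest (input checksums, per-stage row counts, version) sufficient to
re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (
    annotate_sites,
    sample_control_regions,
)
from .errors import ConfigurationError, MidasError
from .genome import (
    BinTrack,
    GenomeLayout,
    IntervalSet,
    load_bin_track,
    read_intervals,
    write_bedgraph,
    write_intervals,
)
from .orientation import (
    RFDTrack,
    classify_sites_orientation,
    orientation_summary,
    read_sv_table,
    site_sv_frequency,
)
from .signal import call_midas_sites, compute_sigma, sites_to_frame, write_sites
from .transcription import (
    SignalTrack,
    classify_transcribed_sites,
    g4_density,
    quantify_tpm,
    rloop_overlap_fraction,
)

INPUT_KEYS = (
    "genome", "counts", "genes", "rt_domains", "origins", "rloops", "g4s",
    "rfd", "eu_plus", "eu_minus", "expression", "svs", "cfs_genes",
)

STAGE_INPUTS = {
    "sigma": ("genome", "counts"),
    "callpeaks": ("genome", "counts"),
    "annotate": ("genes",),
    "controls": ("rt_domains", "rloops", "genes"),
    "rloop": ("rloops",),
    "g4": ("g4s",),
    "transcribe": ("eu_plus", "eu_minus"),
    "expression": ("expression",),
    "orient": ("genes", "rfd"),
    "sv": ("svs",),
}

STAGE_ORDER = ("sigma", "callpeaks", "annotate", "controls", "rloop", "g4",
               "transcribe", "expression", "orient", "sv")


@dataclass
class PipelineConfig:
    """Input paths plus every threshold/window of the analysis battery."""

    inputs: dict[str, str]
    outdir: str
    stages: tuple[str, ...] | None = None   # None: run every stage whose inputs exist
    condition: str = ""
    bin_size: int = 10_000
    sigma_threshold: float = 3.0
    min_run: int = 2
    merge_gap: int = 2
    estimator: str = "robust"
    gene_window: int = 50_000
    overlap_window: int = 600_000
    g4_span: int = 110_000
    sv_window: int = 200_000
    rfd_tau: float = 0.1
    rfd_window: int = 150_000
    flip_rfd: bool = False
    control_n: int = 150
    control_sets: int = 10
    control_exclusion_bins: int = 50
    seed: int = 0

    def __post_init__(self):
        for key in self.inputs:
            if key not in INPUT_KEYS:
                raise ConfigurationError(f"unknown input key {key!r}")
        for name in ("gene_window", "overlap_window", "g4_span", "sv_window", "rfd_window"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.stages is not None:
            for st in self.stages:
                if st not in STAGE_ORDER:
                    raise ConfigurationError(f"unknown stage {st!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat ``key = value`` config file; input paths use the input-key names."""
        inputs, kw = {}, {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"bad config line {raw.strip()!r}")
                key, value = (x.strip() for x in line.split("=", 1))
                if key in INPUT_KEYS:
                    inputs[key] = value
                elif key == "outdir":
                    kw["outdir"] = value
                elif key == "stages":
                    kw["stages"] = tuple(s.strip() for s in value.split(",") if s.strip())
                elif key in fields:
                    current = getattr(cls, key, None)
                    default = cls.__dataclass_fields__[key].default
                    if isinstance(default, bool):
                        kw[key] = value.lower() in ("1", "true", "yes")
                    elif isinstance(default, int):
                        kw[key] = int(value)
                    elif isinstance(default, float):
                        kw[key] = float(value)
                    else:
                        kw[key] = value
                else:
                    raise ConfigurationError(f"unknown config key {key!r}")
        if "outdir" not in kw:
            raise ConfigurationError("config must set outdir")
        return cls(inputs=inputs, **kw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_stages(config: PipelineConfig) -> list[str]:
    have = {k for k, v in config.inputs.items() if v}
    if config.stages is None:
        stages = [st for st in STAGE_ORDER
                  if all(k in have for k in STAGE_INPUTS[st])]
        if "callpeaks" not in stages:
            raise ConfigurationError("stage 'callpeaks' needs inputs: genome, counts")
        return stages
    stages = list(config.stages)
    for needed in ("sigma", "callpeaks"):
        if needed not in stages:
            stages.insert(0, needed)
    stages.sort(key=STAGE_ORDER.index)
    for st in stages:
        for k in STAGE_INPUTS[st]:
            if k not in have:
                raise ConfigurationError(f"stage {st!r} requires input {k!r}")
    return stages


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages in dependency order; returns the report dict."""
    t0 = time.time()
    stages = _resolve_stages(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, path in config.inputs.items():
        if path and not Path(path).exists():
            raise ConfigurationError(f"input {key!r}: no such file {path}")

    layout = GenomeLayout.from_tsv(config.inputs["genome"], config.bin_size)
    counts = load_bin_track(config.inputs["counts"], layout)
    sigma = compute_sigma(counts, estimator=config.estimator)
    write_bedgraph(BinTrack(layout, sigma.sigma, "sigma"), outdir / "sigma.bedgraph")
    sites = call_midas_sites(
        sigma, config.sigma_threshold, config.min_run, config.merge_gap, config.condition
    )
    write_sites(sites, outdir / "sites.tsv")

    loaded: dict[str, IntervalSet] = {}
    for key, kind in (("genes", "gene"), ("rt_domains", "rt_domain"),
                      ("origins", "origin"), ("rloops", "rloop"), ("g4s", "g4")):
        if config.inputs.get(key):
            loaded[key] = read_intervals(config.inputs[key], kind, layout)

    report: dict = {"n_sites": len(sites), "condition": config.condition,
                    "stages": stages}
    rows: dict[str, int] = {"sites": len(sites)}

    if "annotate" in stages:
        cfs = None
        if config.inputs.get("cfs_genes"):
            cfs = [l.strip() for l in open(config.inputs["cfs_genes"]) if l.strip()]
        ann = annotate_sites(
            sites,
            rt_domains=loaded.get("rt_domains"),
            genes=loaded.get("genes"),
            origins=loaded.get("origins"),
            cfs_genes=cfs,
            gene_window=config.gene_window,
        )
        ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        rows["annotations"] = len(ann)
        if sites:
            if "timing" in ann:
                report["rt_distribution"] = ann["timing"].value_counts().to_dict()
            if "genic" in ann:
                report["pct_genic"] = 100.0 * (ann["genic"] == "genic").mean()
        else:
            report["pct_genic"] = None

    if "controls" in stages:
        control_sets = sample_control_regions(
            loaded["rt_domains"], loaded["rloops"], sites, loaded["genes"], layout,
            n=config.control_n, n_sets=config.control_sets,
            exclusion_bins=config.control_exclusion_bins,
            window=config.gene_window, seed=config.seed,
        )
        all_regions = [iv for cs in control_sets for iv in cs.regions]
        write_intervals(all_regions, outdir / "controls.bed")
        rows["control_regions"] = len(all_regions)
        report["n_control_sets"] = len(control_sets)

    if "rloop" in stages:
        if sites:
            r = rloop_overlap_fraction(sites, loaded["rloops"], config.gene_window)
            report["pct_rloop_coincident"] = 100.0 * r["fraction"]
        else:
            report["pct_rloop_coincident"] = None

    if "g4" in stages and sites:
        dens = g4_density(sites, loaded["g4s"], config.g4_span)
        pd.DataFrame({"site_id": [s.site_id for s in sites], "g4_per_kb": dens}).to_csv(
            outdir / "g4_density.tsv", sep="\t", index=False
        )
        report["mean_g4_per_kb"] = float(dens.mean())

    if "transcribe" in stages:
        eu_p = SignalTrack(layout, _load_signal(config.inputs["eu_plus"], layout), "+")
        eu_m = SignalTrack(layout, _load_signal(config.inputs["eu_minus"], layout), "-")
        if sites:
            t = classify_transcribed_sites(sites, eu_p, eu_m, window=config.gene_window)
            report["pct_transcribed"] = 100.0 * t["fraction"]
        else:
            report["pct_transcribed"] = None

    if "expression" in stages:
        expr = pd.read_csv(config.inputs["expression"], sep="\t")
        table = quantify_tpm(expr["count"], expr["length_bp"], expr["gene_id"])
        table.to_csv(outdir / "expression_tpm.tsv", sep="\t", index=False)
        rows["expression"] = len(table)

    if "orient" in stages:
        rfd_track = RFDTrack(layout, _load_signal(config.inputs["rfd"], layout, missing_nan=True))
        if config.flip_rfd:
            rfd_track = rfd_track.negated()
        calls, skipped = classify_sites_orientation(
            sites, loaded["genes"], rfd_track,
            gene_window=config.gene_window, rfd_window=config.rfd_window,
            tau=config.rfd_tau,
        )
        pd.DataFrame(
            {
                "site_id": [c.site_id for c in calls],
                "gene_strand": [c.gene_strand for c in calls],
                "mean_rfd": [c.mean_rfd for c in calls],
                "call": [c.call for c in calls],
            }
        ).to_csv(outdir / "orientation.tsv", sep="\t", index=False)
        rows["orientation_calls"] = len(calls)
        if calls:
            summ = orientation_summary(calls)
            report["orientation"] = {k: summ[k] for k in
                                     ("fraction_codirectional", "fraction_headon",
                                      "fraction_ambiguous", "n")}
        report["orientation_skipped"] = skipped

    if "sv" in stages:
        catalog = read_sv_table(config.inputs["svs"], layout)
        freq = site_sv_frequency(sites, catalog, config.sv_window)
        freq.to_csv(outdir / "sv_frequency.tsv", sep="\t", index=False)
        rows["sv_rows"] = len(freq)
        pct_cols = [c for c in freq.columns if c.startswith("pct_")]
        report["sv_mean_pct"] = {c[4:]: float(freq[c].mean()) for c in pct_cols} if len(freq) else None

    manifest = {
        "version": __version__,
        "config": {**dataclasses.asdict(config), "stages": stages},
        "input_checksums": {k: _sha256(v) for k, v in config.inputs.items() if v},
        "row_counts": rows,
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    report = generate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _load_signal(path, layout: GenomeLayout, missing_nan: bool = False) -> dict[str, np.ndarray]:
    """Load a bedGraph as per-bin float vectors on the layout's grid."""
    track = load_bin_track(path, layout)
    values = {c: np.asarray(v, float) for c, v in track.values.items()}
    if missing_nan:
        # bins not covered by any record stay NaN: reload marking coverage
        covered = {c: np.zeros(layout.n_bins(c), bool) for c in layout.chrom_names}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if chrom in covered:
                    covered[chrom][start // layout.bin_size:(end - 1) // layout.bin_size + 1] = True
        for c in values:
            values[c][~covered[c]] = np.nan
    return values


def generate_report(report: dict) -> dict:
    """Normalize the report: n = 0 runs mark every fraction not-applicable."""
    if report.get("n_sites", 0) == 0:
        for key in ("pct_genic", "pct_rloop_coincident", "pct_transcribed",
                    "mean_g4_per_kb", "rt_distribution", "orientation", "sv_mean_pct"):
            if key in report:
                report[key] = None
    return report
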