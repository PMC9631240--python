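import numpy as np
import pytest

import midasmap as mm


@pytest.fixture()
def toy_layout():
    """Two tiny chromosomes at the default 10-kb bin width."""
    return mm.GenomeLayout(("chr1", "chr2"), (300_000, 200_000), 10_000)


def make_sigma(vec, bin_size=10_000, chrom="chr1"):
    """Wrap a bare sigma vector into a single-chromosome SigmaTrack."""
    vec = np.asarray(vec, float)
    layout = mm.GenomeLayout((chrom,), (len(vec) * bin_size,), bin_size)
    return mm.SigmaTrack(layout, {chrom: vec}, {"estimator": "test"})


@pytest.fixture(scope="session")
def default_world():
    """One synthetic world at the package's default study conditions."""
    cfg = mm.SyntheticConfig()
    truth = mm.generate_world(cfg, 1)
    counts = mm.simulate_bin_counts(truth, cfg, 1)
    catalog = mm.simulate_sv_catalog(truth, cfg, 1)
    return cfg, truth, counts, catalog


@pytest.fixture(scope="session")
def world_dir(default_world, tmp_path_factory):
    cfg, truth, counts, catalog = default_world
    out = tmp_path_factory.mktemp("world")
    mm.write_world(truth, counts, catalog, out, seed=1)
    return out


def match_planted(called_site, truth):
    """A called site recovers a planted site when its anchor lies within
    50 kb of any planted enrichment bump on the same chromosome."""
    return any(
        called_site.chrom == s.chrom
        and any(abs(called_site.anchor - b) <= 50_000 for b in s.bump_positions)
        for s in truth.sites
    )


def recovery_stats(called, truth):
    recalled = sum(
        1
        for s in truth.sites
        if any(
            c.chrom == s.chrom and any(abs(c.anchor - b) <= 50_000 for b in s.bump_positions)
            for c in called
        )
    )
    false_calls = sum(1 for c in called if not match_planted(c, truth))
    recall = recalled / len(truth.sites) if truth.sites else float("nan")
    fdp = false_calls / len(called) if called else 0.0
    return recall, fdp
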