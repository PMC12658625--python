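"""Shared synthetic fixtures.

Everything is generated programmatically under fixed seeds; the "standard"
panel mirrors the study geometry at desk scale: 20 dogs, 16 Italian wolves,
13 European wolves, one outgroup, a 50-Mb chromosome at 1 cM/Mb with 5000
segregating sites and dog-wolf divergence Fst = 0.25.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import wolfintro as wi

STD_SEED = 11


def standard_config(**overrides) -> wi.SimulationConfig:
    kw = dict(n_dog=20, n_wolf_it=16, n_wolf_eu=13, n_outgroup=1,
              chrom_lengths={"1": 50_000_000}, n_sites=5000,
              fst_dog_wolf=0.25, fst_wolf_wolf=0.05, recomb_rate=1.0,
              seed=STD_SEED)
    kw.update(overrides)
    return wi.SimulationConfig(**kw)


@pytest.fixture(scope="session")
def std_config():
    return standard_config()


@pytest.fixture(scope="session")
def std_panel(std_config):
    return wi.simulate_sources(std_config)


@pytest.fixture(scope="session")
def std_gmap(std_config):
    return std_config.genetic_map()


ADMIXED_WOLVES = ["WIT1", "WIT2", "WIT3", "WIT4", "WIT5"]
TRACT_SEED = 1      # all five focal wolves carry tracts under this seed


@pytest.fixture(scope="session")
def admixed(std_panel, std_gmap):
    """Panel with dog tracts (t=5, q=0.15) implanted in five of the sixteen
    Italian wolves (the recent-hybrid geometry), plus the truth tracts."""
    spec = wi.TractSpec(focal_ids=ADMIXED_WOLVES, admix_time_gens=5, admix_fraction=0.15)
    panel, truth = wi.implant_tracts(std_panel, spec, std_gmap, seed=TRACT_SEED)
    return wi.polarize(panel), truth


@pytest.fixture(scope="session")
def std_polarized(std_panel):
    return wi.polarize(std_panel)


RECENT_PLAN = [
    # (sample, target one-haplotype dog fraction, implant seed)
    ("WIT1", 0.5, 500), ("WIT2", 0.5, 520), ("WIT3", 0.25, 541),
    ("WIT4", 0.25, 560), ("WIT5", 0.25, 581),
]


def build_recent_sim():
    """Genome-wide fixture: 8 x 50 Mb, 60k SNPs, five backcross-geometry
    admixed wolves (dog tracts on one haplotype only, t = 7)."""
    chroms = {str(c): 50_000_000 for c in range(1, 9)}
    cfg = wi.SimulationConfig(n_dog=20, n_wolf_it=16, n_wolf_eu=13, n_outgroup=1,
                              chrom_lengths=chroms, n_sites=60_000,
                              fst_dog_wolf=0.25, fst_wolf_wolf=0.05, seed=42)
    panel = wi.simulate_sources(cfg)
    gmap = cfg.genetic_map()
    truths = []
    for sid, q1, seed in RECENT_PLAN:
        spec = wi.TractSpec(focal_ids=[sid], admix_time_gens=7,
                            admix_fraction=q1, haplotypes=(0,))
        panel, tr = wi.implant_tracts(panel, spec, gmap, seed=seed)
        truths.append(tr)
    truth = pd.concat(truths, ignore_index=True)
    return panel, truth, gmap, cfg


@pytest.fixture(scope="session")
def recent_sim():
    return build_recent_sim()


def make_panel(genotypes, populations, haplotypes=None, pos=None, chrom="1",
               chrom_len=None, ancestral=None):
    """Small hand-built panel; genotypes is (n_sites, n_samples)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    pops = list(populations)
    counters: dict[str, int] = {}
    samples = []
    for p in pops:
        counters[p] = counters.get(p, 0) + 1
        samples.append(f"{p}{counters[p]}")
    pos = np.arange(n_sites, dtype=np.int64) * 1000 if pos is None else np.asarray(pos, dtype=np.int64)
    return wi.VariantPanel(
        samples=samples,
        populations=np.asarray(pops, dtype=object),
        chrom=np.asarray([chrom] * n_sites, dtype=object),
        pos=pos,
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["C"] * n_sites, dtype=object),
        genotypes=g,
        haplotypes=None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8),
        ancestral=None if ancestral is None else np.asarray(ancestral, dtype=np.int8),
        chrom_lengths={chrom: int(chrom_len if chrom_len is not None else pos.max() + 1000)},
    )
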