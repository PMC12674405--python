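import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from sweepscan import SweepSimConfig, simulate_sweep_dataset
from sweepscan.simulate import emit_dataset
from sweepscan.variant_io import HaplotypeMatrix


def tiny_sim_config(seed: int = 1, **kw) -> SweepSimConfig:
    """Desk-scale-but-small config used by fast unit tests."""
    defaults = dict(n_pop1=15, n_pop2=15, n_sites=300, region_bp=1_000_000,
                    sweep_pos_bp=500_000, seed=seed)
    defaults.update(kw)
    return SweepSimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_sweep():
    cfg = tiny_sim_config()
    hap1, hap2, truth = simulate_sweep_dataset(cfg)
    return cfg, hap1, hap2, truth


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    cfg = tiny_sim_config()
    paths = emit_dataset(cfg, str(out))
    return cfg, paths


def random_haplotypes(rng: np.random.Generator, n_haps: int, n_sites: int,
                      spacing_bp: int = 1000) -> HaplotypeMatrix:
    """Unstructured random haplotypes on an even grid (for oracle tests)."""
    alleles = rng.integers(0, 2, (n_haps, n_sites)).astype(np.uint8)
    pos = np.arange(1, n_sites + 1, dtype=np.int64) * spacing_bp
    return HaplotypeMatrix(alleles, pos, pos * 1e-6,
                           [f"s{i // 2}" for i in range(n_haps)])
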