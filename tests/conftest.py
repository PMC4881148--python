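import sys
from pathlib import Path

import pytest

TESTS_DIR = Path(__file__).resolve().parent
REPO_DIR = TESTS_DIR.parent
for extra in (TESTS_DIR, REPO_DIR / "scripts"):
    if str(extra) not in sys.path:
        sys.path.insert(0, str(extra))

from repeatchip.synthetic_data import (GenomeSpec, RepeatFamilySpec,
                                       build_synthetic_genome,
                                       simulate_shotgun_pairs)


@pytest.fixture(scope="session")
def satellite_genome():
    """Small genome: one undiverged 327 nt-monomer satellite + background."""
    spec = GenomeSpec(
        families=[RepeatFamilySpec("satA", "satellite", 327, 20, divergence=0.0)],
        background_length=20000, seed=7)
    return build_synthetic_genome(spec)


@pytest.fixture(scope="session")
def satellite_reads(satellite_genome):
    pairs = simulate_shotgun_pairs(satellite_genome, coverage=1.0,
                                   read_length=100, insert_size=300, seed=8)
    return pairs


@pytest.fixture(scope="session")
def demo_config_path():
    return REPO_DIR / "configs" / "demo.yaml"


@pytest.fixture(scope="session")
def demo_run(demo_config_path, tmp_path_factory):
    """One full pipeline run shared by the pipeline/CLI tests."""
    from repeatchip.pipeline import run_pipeline
    outdir = tmp_path_factory.mktemp("demo") / "run"
    return run_pipeline(demo_config_path, outdir=outdir)
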