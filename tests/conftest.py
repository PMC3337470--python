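import numpy as np
import pytest

from coaldrop.coalescent import ChromosomeSpec, simulate_panel
from coaldrop.demography import NeTrajectory
from coaldrop.io_cli.specfile import parse_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def const_ne_100():
    return NeTrajectory((0.0,), (100.0,))


@pytest.fixture(scope="session")
def const_ne_1000():
    return NeTrajectory((0.0,), (1000.0,))


@pytest.fixture(scope="session")
def small_panel():
    """A modest panel reused by gene-drop and marker tests."""
    chrom = ChromosomeSpec(1, 100.0, 500_000, 2.5e-7)
    traj = NeTrajectory((0.0,), (500.0,))
    return simulate_panel(60, chrom, traj, np.random.default_rng(99))


TINY_SCENARIO = """
[genome]
chromosomes = 2
genetic_length_cm = 100
physical_length_bp = 100000
mutation_rate = 2.5e-7

[demography]
ne = 0 100
ne = 1000 1256

[haplotypes]
source = internal
n_haplotypes = 40

[pedigree]
source = internal
generations = 4
sires_per_generation = 3
dams_per_sire = 2
offspring_per_dam = 3

[chips]
chip = lo 15
chip = hi 40

[qtl]
count = 25
maf_threshold = 0.3

[traits]
trait = PolyUnres unrestricted normal all 0.25
trait = GammaUnres unrestricted gamma:0.4:1.66 8 0.25
trait = PolyRes restricted normal all 0.25
trait = GammaRes restricted gamma:0.4:1.66 8 0.25

[split]
training_generations = 1 2
validation = 3:5

[run]
seed = 7
write_sequence = true
write_phased = true
write_vcf = true
"""


@pytest.fixture(scope="session")
def tiny_spec():
    return parse_spec(TINY_SCENARIO)


@pytest.fixture(scope="session")
def tiny_run(tiny_spec, tmp_path_factory):
    from coaldrop.io_cli.pipeline import run

    out = tmp_path_factory.mktemp("tiny_run")
    run(tiny_spec, out)
    return out
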