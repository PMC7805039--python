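import pathlib
import sys

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(pathlib.Path(__file__).parent))

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gwasvcfkit.pipeline import convert_sumstats  # noqa: E402
from gwasvcfkit.synthdata import (  # noqa: E402
    SimulationConfig,
    make_reference,
    simulate_sumstats,
)
from gwasvcfkit.vcf_io import merge_traits  # noqa: E402


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One-trait synthetic dataset (~1000 rows) with all perturbations."""
    out = tmp_path_factory.mktemp("small_sim")
    config = SimulationConfig(
        seed=7,
        contig_lengths=(60_000, 40_000),
        variants_per_contig=(600, 400),
        n_traits=1,
        n_incompatible=10,
    )
    reference = make_reference(config, out_dir=out)
    return simulate_sumstats(config, reference, out)


@pytest.fixture(scope="session")
def small_vcf(small_sim, tmp_path_factory):
    """The small dataset converted to an indexed GWAS-VCF."""
    out = tmp_path_factory.mktemp("small_vcf") / "trait_1.vcf.gz"
    report = convert_sumstats(
        small_sim.tables["trait_1"],
        small_sim.schema_path,
        small_sim.reference.fasta_path,
        out,
        metadata=small_sim.metadata[0],
    )
    return out, report, small_sim


@pytest.fixture(scope="session")
def duo_vcf(tmp_path_factory):
    """Two-trait merged GWAS-VCF over shared loci (small)."""
    out = tmp_path_factory.mktemp("duo")
    config = SimulationConfig(
        seed=19,
        contig_lengths=(60_000, 40_000),
        variants_per_contig=(500, 300),
        n_traits=2,
        corrupt_fraction=0.0,
        n_incompatible=0,
    )
    reference = make_reference(config, out_dir=out)
    sim = simulate_sumstats(config, reference, out)
    singles = []
    for trait, table in sim.tables.items():
        p = out / f"{trait}.vcf.gz"
        convert_sumstats(table, sim.schema_path, reference.fasta_path, p,
                         metadata=sim.metadata[sim.config.trait_ids().index(trait)])
        singles.append(p)
    merged = out / "merged.vcf.gz"
    merge_traits(singles, merged)
    return merged, singles, sim
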