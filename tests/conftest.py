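import numpy as np
import pytest

from bsapilla import simdata


def f2_expected_nonp1_freq(phenotype: str, dominant: bool = True) -> float:
    """Independent oracle: exact non-P1 allele frequency in a phenotype class.

    Enumerates the four equiprobable F1 gamete pairs, conditions on the
    phenotype at the causal locus, and averages the P2-allele dosage.
    """
    num = den = 0.0
    for a in (0, 1):  # P2 alleles contributed by each gamete
        for b in (0, 1):
            g = a + b
            papilla = (g <= 1) if dominant else (g == 0)
            if (phenotype == "papilla") == papilla:
                num += g / 2.0
                den += 1.0
    return num / den


def f2_expected_delta(dominant: bool = True) -> float:
    """Exact expected delta index (non-papilla minus papilla bulk)."""
    return f2_expected_nonp1_freq("non-papilla", dominant) - f2_expected_nonp1_freq(
        "papilla", dominant
    )


@pytest.fixture(scope="session")
def small_spec() -> simdata.GenomeSpec:
    """Two 5-Mb chromosomes, causal locus mid-chromosome-1."""
    return simdata.GenomeSpec(
        chromosomes=[
            simdata.ChromosomeSpec("chr1", 5_000_000),
            simdata.ChromosomeSpec("chr2", 5_000_000),
        ],
        markers_per_chromosome=40,
        causal_locus=("chr1", 2_500_000),
        indel_fraction=0.2,
    )


@pytest.fixture(scope="session")
def small_sim(small_spec):
    """One simulated population + bulks + reads on the small genome."""
    mm = simdata.build_marker_map(small_spec, seed=11)
    pop = simdata.simulate_f2_population(mm, 240, seed=11)
    bulks = simdata.make_bulks(pop, 30, seed=11)
    reads = (
        simdata.sequence_bulk(bulks[0], 50.0, 0.0, seed=11),
        simdata.sequence_bulk(bulks[1], 50.0, 0.0, seed=12),
    )
    return {"spec": small_spec, "map": mm, "pop": pop, "bulks": bulks, "reads": reads}


@pytest.fixture(scope="session")
def fixture_dir(small_sim, tmp_path_factory):
    """File fixture set written from the small simulation."""
    outdir = tmp_path_factory.mktemp("fixture_set")
    paths = simdata.write_fixture_set(
        outdir,
        small_sim["spec"],
        small_sim["pop"],
        small_sim["bulks"],
        small_sim["reads"],
        seed=11,
        gene_length=20_000,
        gene_spacing=250_000,
    )
    return paths
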