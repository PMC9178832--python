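"""Shared fixtures: synthetic reference and planted genomes."""

from __future__ import annotations

import numpy as np
import pytest

from hml9map import discovery, synthetic


@pytest.fixture(scope="session")
def reference():
    """Synthetic proviral reference with the canonical region map."""
    return synthetic.make_reference(42)


@pytest.fixture(scope="session")
def planted():
    """A two-chromosome genome with four planted elements of known truth."""
    ref = synthetic.make_reference(42)
    cfg = synthetic.GenomeConfig(
        chromosomes={"chr1": 300_000, "chr2": 200_000},
        n_genes=10,
        plants=(
            synthetic.PlantSpec(
                "full_provirus", "chr1", "+", true_age_my=20.0,
                context_target="intergenic",
            ),
            synthetic.PlantSpec(
                "solo_LTR", "chr1", "-", true_age_my=30.0,
                context_target="intron",
            ),
            synthetic.PlantSpec(
                "deleted_provirus", "chr2", "-", true_age_my=10.0,
                deletions=((3411, 4735),), context_target="intergenic",
            ),
            synthetic.PlantSpec(
                "solo_LTR", "chr2", "+", true_age_my=15.0,
                context_target="intergenic",
            ),
        ),
    )
    genome, genes, truth, _ = synthetic.generate_genome(cfg, 7, reference=ref)
    return ref, genome, genes, truth


@pytest.fixture(scope="session")
def planted_loci(planted):
    """Discovered loci on the planted genome."""
    ref, genome, genes, truth = planted
    index = discovery.build_index(genome)
    chains = discovery.search(ref, index, genome)
    return discovery.merge_chains_to_loci(chains, ref)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))
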