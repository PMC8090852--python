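"""Shared fixtures: toy genomes, TE libraries, and simulated datasets.

Everything is generated programmatically with fixed seeds; the heavier
simulations are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from teclone import simkit


@pytest.fixture(scope="session")
def te_library():
    return simkit.build_te_library(7)


@pytest.fixture(scope="session")
def toy_genome():
    return simkit.build_reference(1, {"chr2L": 100_000, "chr3R": 80_000}, 0.42)


@pytest.fixture(scope="session")
def reference_map(toy_genome):
    return {r.id: r.sequence for r in toy_genome}


@pytest.fixture(scope="session")
def two_implant_sim(toy_genome, te_library):
    """Two clonal implants (one minus-strand, truncated) at 50x, error-free."""
    specs = [
        simkit.ImplantSpec("rover", "chr2L", 50_000, tsd_length=5),
        simkit.ImplantSpec(
            "copia", "chr3R", 30_000, strand="-", tsd_length=8, truncation_5p=13
        ),
    ]
    by_chrom, manifest = simkit.implant(toy_genome, te_library, specs, 1)
    gold = simkit.simulate_short_reads(
        toy_genome, te_library, by_chrom, manifest, coverage=50, seed=2
    )
    return gold


@pytest.fixture(scope="session")
def clean_sim(toy_genome, te_library):
    """Insertion-free control simulation at 30x."""
    by_chrom, manifest = simkit.implant(toy_genome, te_library, [], 0)
    return simkit.simulate_short_reads(
        toy_genome, te_library, by_chrom, manifest, coverage=30, seed=5
    )


def random_implants(genome, te_library, rng, n, cell_fraction=1.0, zygosity="hemizygous"):
    """Non-overlapping random implant specs across the genome."""
    fams = [r.id for r in te_library]
    specs = []
    for chrom_rec in genome:
        L = len(chrom_rec.sequence)
        k = max(1, int(round(n * L / sum(len(g.sequence) for g in genome))))
        pos = np.sort(rng.choice(np.arange(15_000, L - 15_000, 1_500), size=k, replace=False))
        for i, p in enumerate(pos):
            specs.append(
                simkit.ImplantSpec(
                    te_family=fams[int(rng.integers(0, len(fams)))],
                    target_chrom=chrom_rec.id,
                    target_pos=int(p),
                    strand="+" if rng.random() < 0.5 else "-",
                    tsd_length=int(rng.integers(3, 13)),
                    cell_fraction=cell_fraction,
                    zygosity=zygosity,
                )
            )
    return specs[:n]
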