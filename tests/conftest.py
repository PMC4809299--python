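import numpy as np
import pandas as pd
import pytest

from namqtl import simulate as sim
from namqtl.types import GeneticMap, GenotypeMatrix, QTLModel, VarianceSpec


@pytest.fixture(scope="session")
def small_map():
    return sim.make_genetic_map(3, 120.0, 30)


@pytest.fixture(scope="session")
def small_population(small_map):
    return sim.build_nam_population(small_map, 5, 60, seed=101)


@pytest.fixture(scope="session")
def qtl_trait(small_map, small_population):
    """Population + a two-QTL trait with known effects and mild noise."""
    model = sim.draw_qtl_model(
        small_map, 2, 1.0, seed=102, min_spacing_cm=40.0
    )
    genetic = sim.qtl_genetic_values(small_population, model)
    rng = np.random.default_rng(103)
    blues = pd.Series(
        genetic + rng.normal(0.0, 1.0, small_population.n_lines),
        index=small_population.line_ids,
    )
    return small_population, model, blues


def make_genotypes(dosage, families=None, marker_ids=None, line_ids=None):
    """Hand-built GenotypeMatrix for constructed test cases."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        line_ids=np.array(
            line_ids if line_ids is not None else [f"L{i:03d}" for i in range(n)],
            dtype=object,
        ),
        families=np.array(
            families if families is not None else ["F1"] * n, dtype=object
        ),
        marker_ids=tuple(
            marker_ids if marker_ids is not None else [f"m{j}" for j in range(m)]
        ),
        dosage=dosage,
    )


def make_map(marker_ids, chromosomes, positions):
    return GeneticMap(
        marker_ids=tuple(marker_ids),
        chromosomes=tuple(chromosomes),
        positions_cm=np.asarray(positions, dtype=float),
    )


def balanced_records(line_effects, year_effects, mu=0.0, reps=2, trait="trait",
                     noise=None, rng=None):
    """Noise-free (or N(0, noise^2)) balanced two-way phenotype table."""
    rows = []
    for line, g in line_effects.items():
        for year, e in year_effects.items():
            for rep in range(1, reps + 1):
                value = mu + g + e
                if noise:
                    value += rng.normal(0.0, noise)
                rows.append(
                    {"line_id": line, "year": year, "rep": rep,
                     "trait": trait, "value": value}
                )
    return pd.DataFrame(rows)
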