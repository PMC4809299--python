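"""Synthetic multi-family backcross-selfing (BC1S3) populations.

The crossing scheme is: donor x recurrent -> F1; F1 x recurrent -> BC1;
three generations of selfing with independent meioses -> BC1S3.  Donor and
recurrent parents are fully inbred, so the F1 is heterozygous at every
polymorphic marker.  Meioses follow the Haldane model (no interference):
the recombination fraction between loci d cM apart is 0.5*(1 - exp(-2d/100)).

Expected single-locus genotype frequencies in BC1S3 material are
P(dosage 0) = 23/32, P(1) = 1/16, P(2) = 7/32, and the expected donor-genome
fraction is 25%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from namqtl.types import (
    ConfigurationError,
    GeneticMap,
    GenotypeMatrix,
    QTLModel,
    VarianceSpec,
)

__all__ = [
    "haldane_recombination_fraction",
    "make_genetic_map",
    "simulate_bc1s3_family",
    "build_nam_population",
    "draw_qtl_model",
    "simulate_phenotypes",
    "simulate_daily_temperatures",
]


def haldane_recombination_fraction(distance_cm):
    """Recombination fraction for loci ``distance_cm`` apart (Haldane)."""
    d = np.asarray(distance_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_genetic_map(
    n_chromosomes: int,
    chrom_lengths_cm,
    markers_per_chrom,
    spacing: str = "regular",
    seed=None,
) -> GeneticMap:
    """Build a marker map with regular or uniformly random spacing.

    ``chrom_lengths_cm`` and ``markers_per_chrom`` may be scalars (applied to
    all chromosomes) or per-chromosome sequences.
    """
    if n_chromosomes < 1:
        raise ConfigurationError("n_chromosomes must be >= 1")
    lengths = np.broadcast_to(
        np.asarray(chrom_lengths_cm, dtype=float), (n_chromosomes,)
    )
    counts = np.broadcast_to(np.asarray(markers_per_chrom, dtype=int), (n_chromosomes,))
    if np.any(lengths <= 0):
        raise ConfigurationError("chromosome lengths must be > 0")
    if np.any(counts < 2):
        raise ConfigurationError("markers_per_chrom must be >= 2")
    if spacing not in ("regular", "uniform"):
        raise ConfigurationError(f"unknown spacing {spacing!r}")
    rng = _as_rng(seed)

    marker_ids, chroms, positions = [], [], []
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        m = int(counts[c])
        if spacing == "regular":
            pos = np.linspace(0.0, lengths[c], m)
        else:
            pos = np.sort(rng.uniform(0.0, lengths[c], size=m))
        width = len(str(m))
        for j in range(m):
            marker_ids.append(f"{chrom}_m{j + 1:0{width}d}")
            chroms.append(chrom)
            positions.append(pos[j])
    return GeneticMap(
        marker_ids=tuple(marker_ids),
        chromosomes=tuple(chroms),
        positions_cm=np.asarray(positions),
    )


def _meiosis(haplotypes: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """Draw one gamete per individual from (n, 2, m) parental haplotypes.

    Per chromosome: the starting haplotype is chosen uniformly and switches
    between adjacent markers occur independently with the Haldane
    recombination fraction (Markov crossover process, no interference).
    """
    n, _, m = haplotypes.shape
    gametes = np.empty((n, m), dtype=haplotypes.dtype)
    for chrom, sl in gmap.chromosome_slices().items():
        pos = gmap.positions_cm[sl]
        rec = haldane_recombination_fraction(np.diff(pos))
        k = pos.size
        start = rng.integers(0, 2, size=n)
        if k > 1:
            switches = rng.random((n, k - 1)) < rec
            choice = np.empty((n, k), dtype=np.int64)
            choice[:, 0] = start
            choice[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
        else:
            choice = start[:, None]
        rows = np.arange(n)[:, None]
        cols = np.arange(sl.start, sl.stop)[None, :]
        gametes[:, sl] = haplotypes[rows, choice, cols]
    return gametes


def simulate_bc1s3_family(
    gmap: GeneticMap,
    n_lines: int,
    seed=None,
    family: str = "F01",
    line_prefix: str | None = None,
    n_selfings: int = 3,
) -> GenotypeMatrix:
    """Simulate one BC1-derived selfing family of ``n_lines`` lines.

    The donor carries the wild allele (1) at every marker and the recurrent
    parent the cultivated allele (0); dosages therefore count wild alleles.
    ``n_selfings`` defaults to the BC1S3 scheme (three selfing generations).
    """
    if n_lines < 1:
        raise ConfigurationError("n_lines must be >= 1")
    if n_selfings < 0:
        raise ConfigurationError("n_selfings must be >= 0")
    rng = _as_rng(seed)
    m = gmap.n_markers

    # F1: one full donor haplotype, one full recurrent haplotype.
    f1 = np.zeros((n_lines, 2, m), dtype=np.int8)
    f1[:, 0, :] = 1
    # BC1 = gamete(F1) + recurrent gamete (all zeros).
    genomes = np.zeros((n_lines, 2, m), dtype=np.int8)
    genomes[:, 0, :] = _meiosis(f1, gmap, rng)
    # Rounds of selfing, two independent meioses each.
    for _ in range(n_selfings):
        next_gen = np.empty_like(genomes)
        next_gen[:, 0, :] = _meiosis(genomes, gmap, rng)
        next_gen[:, 1, :] = _meiosis(genomes, gmap, rng)
        genomes = next_gen

    dosage = genomes.sum(axis=1).astype(float)
    prefix = line_prefix if line_prefix is not None else family
    width = len(str(n_lines))
    line_ids = np.array(
        [f"{prefix}_L{i + 1:0{width}d}" for i in range(n_lines)], dtype=object
    )
    return GenotypeMatrix(
        line_ids=line_ids,
        families=np.full(n_lines, family, dtype=object),
        marker_ids=gmap.marker_ids,
        dosage=dosage,
    )


def build_nam_population(
    gmap: GeneticMap,
    n_families: int,
    lines_per_family,
    polymorphism_rate_per_family: float = 1.0,
    seed=None,
) -> GenotypeMatrix:
    """Concatenate BC1S3 families into one NAM population.

    Each marker segregates (donor differs from recurrent) in an independent
    Bernoulli subset of families; in the remaining families the marker is
    monomorphic and all its lines carry dosage 0.
    """
    if n_families < 1:
        raise ConfigurationError("n_families must be >= 1")
    rate = float(polymorphism_rate_per_family)
    if not (0.0 < rate <= 1.0):
        raise ConfigurationError("polymorphism_rate_per_family must be in (0, 1]")
    sizes = np.broadcast_to(np.asarray(lines_per_family, dtype=int), (n_families,))
    if np.any(sizes < 1):
        raise ConfigurationError("lines_per_family must be >= 1")
    rng = _as_rng(seed)

    width = len(str(n_families))
    blocks = []
    for f in range(n_families):
        family = f"F{f + 1:0{width}d}"
        block = simulate_bc1s3_family(gmap, int(sizes[f]), seed=rng, family=family)
        if rate < 1.0:
            monomorphic = rng.random(gmap.n_markers) >= rate
            block.dosage[:, monomorphic] = 0.0
        blocks.append(block)
    return GenotypeMatrix(
        line_ids=np.concatenate([b.line_ids for b in blocks]),
        families=np.concatenate([b.families for b in blocks]),
        marker_ids=gmap.marker_ids,
        dosage=np.vstack([b.dosage for b in blocks]),
    )


def draw_qtl_model(
    gmap: GeneticMap,
    n_qtl: int,
    effect_sizes,
    family_specific_fraction: float = 0.0,
    seed=None,
    min_spacing_cm: float = 0.0,
    families=None,
    intercept: float = 0.0,
) -> QTLModel:
    """Place ``n_qtl`` additive QTLs at marker positions.

    ``effect_sizes`` is a scalar or length-``n_qtl`` sequence of per-dosage
    coefficients.  A ``family_specific_fraction`` of the QTLs is restricted to
    a strict random subset of ``families`` (required when the fraction is >0).
    """
    if n_qtl < 0 or n_qtl > gmap.n_markers:
        raise ConfigurationError("n_qtl must be in [0, n_markers]")
    if not (0.0 <= family_specific_fraction <= 1.0):
        raise ConfigurationError("family_specific_fraction must be in [0, 1]")
    if family_specific_fraction > 0 and (families is None or len(families) < 2):
        raise ConfigurationError(
            "family-specific QTLs require >= 2 family labels"
        )
    effects = np.broadcast_to(np.asarray(effect_sizes, dtype=float), (n_qtl,))
    rng = _as_rng(seed)

    if n_qtl == 0:
        return QTLModel(marker_indices=(), effects=(), intercept=intercept)

    chroms = np.asarray(gmap.chromosomes, dtype=object)
    order = rng.permutation(gmap.n_markers)
    chosen: list[int] = []
    for j in order:
        ok = all(
            chroms[j] != chroms[i]
            or abs(gmap.positions_cm[j] - gmap.positions_cm[i]) >= min_spacing_cm
            for i in chosen
        )
        if ok:
            chosen.append(int(j))
        if len(chosen) == n_qtl:
            break
    if len(chosen) < n_qtl:
        raise ConfigurationError(
            f"cannot place {n_qtl} QTLs with min spacing {min_spacing_cm} cM"
        )
    chosen.sort()

    n_specific = int(round(family_specific_fraction * n_qtl))
    specific = set(rng.choice(n_qtl, size=n_specific, replace=False).tolist())
    masks = []
    for q in range(n_qtl):
        if q in specific:
            k = int(rng.integers(1, len(families)))  # strict subset
            masks.append(frozenset(rng.choice(list(families), size=k, replace=False)))
        else:
            masks.append(None)
    return QTLModel(
        marker_indices=tuple(chosen),
        effects=tuple(effects),
        family_masks=tuple(masks),
        intercept=intercept,
    )


def qtl_genetic_values(genotypes: GenotypeMatrix, qtl_model: QTLModel) -> np.ndarray:
    """Per-line sum of QTL contributions (respecting family masks)."""
    values = np.full(genotypes.n_lines, qtl_model.intercept, dtype=float)
    dosage = np.nan_to_num(genotypes.dosage, nan=0.0)
    for idx, beta, mask in zip(
        qtl_model.marker_indices, qtl_model.effects, qtl_model.family_masks
    ):
        contrib = beta * dosage[:, idx]
        if mask is not None:
            active = np.isin(genotypes.families, list(mask))
            contrib = np.where(active, contrib, 0.0)
        values += contrib
    return values


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    qtl_model: QTLModel,
    variance_spec: VarianceSpec,
    seed=None,
    trait: str = "trait",
    year_sd: float = 1.0,
    reps_per_year=None,
) -> pd.DataFrame:
    """Simulate plot-level records for all lines over years and replicates.

    value(line, year, rep) = intercept + QTL sum + g_line + year effect
    + (g x year) + residual, with g ~ N(0, v_g), gy ~ N(0, v_gy),
    residual ~ N(0, v_r), and one N(0, year_sd^2) main effect per year.
    ``reps_per_year`` optionally unbalances the design (e.g. (1, 2, 2, 1)).
    """
    rng = _as_rng(seed)
    n = genotypes.n_lines
    y, r = variance_spec.years, variance_spec.reps
    if reps_per_year is None:
        reps = [r] * y
    else:
        reps = [int(v) for v in reps_per_year]
        if len(reps) != y or any(v < 1 for v in reps):
            raise ConfigurationError("reps_per_year must give >= 1 rep for each year")

    genetic = qtl_genetic_values(genotypes, qtl_model)
    g = rng.normal(0.0, np.sqrt(variance_spec.v_g), size=n)
    year_effects = rng.normal(0.0, year_sd, size=y)
    gy = rng.normal(0.0, np.sqrt(variance_spec.v_gy), size=(n, y))

    rows = []
    for j in range(y):
        year = 2011 + j
        for rep in range(1, reps[j] + 1):
            eps = rng.normal(0.0, np.sqrt(variance_spec.v_r), size=n)
            values = genetic + g + year_effects[j] + gy[:, j] + eps
            rows.append(
                pd.DataFrame(
                    {
                        "line_id": genotypes.line_ids,
                        "year": year,
                        "rep": rep,
                        "trait": trait,
                        "value": values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_daily_temperatures(
    n_days: int,
    mean: float = 10.0,
    amplitude: float = 8.0,
    noise_sd: float = 2.0,
    seed=None,
    period_days: float = 365.0,
) -> np.ndarray:
    """Sinusoid-plus-noise daily mean temperatures (deg C); may be negative."""
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    rng = _as_rng(seed)
    day = np.arange(n_days, dtype=float)
    temps = mean + amplitude * np.sin(2.0 * np.pi * day / period_days)
    if noise_sd > 0:
        temps = temps + rng.normal(0.0, noise_sd, size=n_days)
    return temps
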