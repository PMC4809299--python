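"""Resampling layer: detection rates, QTL consolidation, predictive ability.

The full association procedure (cofactor selection, genome scan, Holm
adjustment) is re-run on repeated family-stratified 80% subsamples.  A
marker's detection rate is the fraction of runs in which it is significant;
markers reaching the detection threshold are chained into QTL intervals when
consecutive qualifying markers lie closer than the merge distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from namqtl.gwas import (
    CofactorSet,
    _align_blues,
    _independent_columns,
    family_design,
    impute_family_mean,
    scan_genome,
    select_cofactors,
)
from namqtl.types import ConfigurationError, GeneticMap, GenotypeMatrix

__all__ = [
    "SubsampleSplit",
    "stratified_subsample",
    "adjusted_r2",
    "JointMarkerModel",
    "fit_joint_model",
    "predictive_ability",
    "run_cross_validated_gwas",
    "CVResult",
    "consolidate_qtl",
    "QTLRecord",
    "combine_marker_tables",
    "qtl_summary_table",
]


@dataclass(frozen=True)
class SubsampleSplit:
    run: int
    training_idx: np.ndarray
    holdout_idx: np.ndarray

    def __post_init__(self):
        overlap = np.intersect1d(self.training_idx, self.holdout_idx)
        if overlap.size:
            raise ConfigurationError("training and holdout sets overlap")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_subsample(
    line_ids, family_labels, fraction: float = 0.8, seed=None, run: int = 0
) -> SubsampleSplit:
    """Sample ~``fraction`` of the lines per family, without replacement.

    Per family, round-half-up(fraction * n) lines enter training, clamped so
    that at least one line is held out and at least one trains.  Families of
    size 1 cannot be stratified and raise.
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError("fraction must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    line_ids = np.asarray(line_ids, dtype=object)
    families = np.asarray(family_labels, dtype=object)

    training, holdout = [], []
    for fam in dict.fromkeys(families):
        idx = np.flatnonzero(families == fam)
        if idx.size < 2:
            raise ConfigurationError(
                f"family {fam!r} has {idx.size} line(s); cannot stratify"
            )
        n_train = min(max(_round_half_up(fraction * idx.size), 1), idx.size - 1)
        chosen = rng.choice(idx, size=n_train, replace=False)
        training.append(np.sort(chosen))
        holdout.append(np.setdiff1d(idx, chosen))
    return SubsampleSplit(
        run=run,
        training_idx=np.concatenate(training),
        holdout_idx=np.concatenate(holdout),
    )


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Ezekiel's adjusted R^2 = 1 - (1 - R^2) * (n - 1) / (n - k - 1)."""
    if n <= k + 1:
        raise ValueError("adjusted R^2 requires n > k + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass
class JointMarkerModel:
    """Family intercepts plus jointly re-estimated marker effects."""

    family_levels: list
    marker_ids: tuple
    coef: np.ndarray  # aligned with [family design | kept marker columns]
    kept_marker_cols: list
    r2: float
    n_train: int

    def predict(self, genotypes: GenotypeMatrix, dosage: np.ndarray | None = None):
        base, levels = family_design(genotypes.families)
        if levels != self.family_levels:
            # Rebuild the family design against the training levels so that
            # holdout rows map onto training contrasts.
            fams = np.asarray(genotypes.families, dtype=object)
            base = np.ones((len(fams), len(self.family_levels)))
            for j, level in enumerate(self.family_levels[1:], start=1):
                base[:, j] = (fams == level).astype(float)
        if dosage is None:
            dosage = impute_family_mean(genotypes)
        cols = [genotypes.marker_ids.index(m) for m in self.marker_ids]
        x = np.column_stack([base] + [dosage[:, c] for c in cols])
        x = x[:, list(range(base.shape[1])) + [base.shape[1] + i for i in self.kept_marker_cols]]
        return x @ self.coef


def fit_joint_model(
    genotypes: GenotypeMatrix, blues, markers, family_labels=None
) -> JointMarkerModel:
    """OLS fit of intercept + family + all given markers on training lines.

    Rank-deficient marker columns (e.g. duplicated SNPs in a small training
    family) are dropped with a warning and the model is refit on the rest.
    """
    y = _align_blues(genotypes, blues)
    families = np.asarray(
        family_labels if family_labels is not None else genotypes.families,
        dtype=object,
    )
    base, levels = family_design(families)
    dosage = impute_family_mean(genotypes)
    markers = tuple(markers)
    cols = [genotypes.marker_ids.index(m) for m in markers]
    marker_block = (
        dosage[:, cols] if cols else np.empty((genotypes.n_lines, 0))
    )
    x = np.column_stack([base, marker_block])

    keep_all = _independent_columns(x)
    base_cols = list(range(base.shape[1]))
    kept_marker_cols = [j - base.shape[1] for j in keep_all if j >= base.shape[1]]
    if len(kept_marker_cols) < len(markers):
        warnings.warn(
            f"dropped {len(markers) - len(kept_marker_cols)} rank-deficient "
            "marker column(s) from the joint model",
            stacklevel=2,
        )
    kept = [j for j in keep_all if j in base_cols] + [
        base.shape[1] + i for i in kept_marker_cols
    ]
    x = x[:, kept]
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(((y - fitted) ** 2).sum())
    r2 = max(0.0, 1.0 - rss / tss) if tss > 0 else 0.0
    return JointMarkerModel(
        family_levels=levels,
        marker_ids=markers,
        coef=coef,
        kept_marker_cols=kept_marker_cols,
        r2=r2,
        n_train=y.size,
    )


def predictive_ability(
    model: JointMarkerModel,
    holdout_genotypes: GenotypeMatrix,
    holdout_blues,
    holdout_dosage: np.ndarray | None = None,
) -> float:
    """Squared Pearson correlation of predicted vs observed holdout values.

    NaN when the predictions (or observations) have zero variance.
    """
    observed = _align_blues(holdout_genotypes, holdout_blues)
    predicted = model.predict(holdout_genotypes, dosage=holdout_dosage)
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return float("nan")
    r = np.corrcoef(predicted, observed)[0, 1]
    return float(r * r)


@dataclass
class CVResult:
    """Aggregated output of the repeated-subsampling association procedure."""

    marker_table: pd.DataFrame
    run_table: pd.DataFrame
    n_runs: int
    mean_r2_adj: float
    mean_r2_pred: float


def run_cross_validated_gwas(
    genotypes: GenotypeMatrix,
    blues,
    family_labels=None,
    gmap: GeneticMap | None = None,
    n_runs: int = 200,
    fraction: float = 0.8,
    base_seed: int = 0,
    alpha: float = 0.05,
    exclusion_window_cm: float = 1.0,
    max_cofactors: int | None = None,
) -> CVResult:
    """Re-run cofactor selection + scan + Holm on stratified subsamples.

    Per-marker effects, adjusted p-values and R^2 are averaged over the runs
    in which the marker was significant.  Per run, all significant markers
    are re-fit jointly on the training lines to obtain R^2_adj (k counts
    marker coefficients only) and the model predicts the held-out 20% for
    R^2_pred.  Child run seeds are spawned from ``base_seed`` via
    ``numpy.random.SeedSequence(base_seed).spawn(n_runs)``.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    if gmap is None:
        raise ConfigurationError("run_cross_validated_gwas requires a genetic map")
    families = np.asarray(
        family_labels if family_labels is not None else genotypes.families,
        dtype=object,
    )
    y_full = _align_blues(genotypes, blues)
    m = genotypes.n_markers

    det_count = np.zeros(m, dtype=int)
    sum_beta = np.zeros(m)
    sum_p = np.zeros(m)
    sum_r2 = np.zeros(m)

    child_seeds = np.random.SeedSequence(base_seed).spawn(n_runs)
    run_rows = []
    for run in range(n_runs):
        rng = np.random.default_rng(child_seeds[run])
        split = stratified_subsample(
            genotypes.line_ids, families, fraction=fraction, seed=rng, run=run
        )
        train = genotypes.subset_lines(split.training_idx)
        hold = genotypes.subset_lines(split.holdout_idx)
        y_train = y_full[split.training_idx]
        y_hold = y_full[split.holdout_idx]

        cofactors = select_cofactors(
            train, y_train, gmap=gmap, max_cofactors=max_cofactors
        )
        scan = scan_genome(
            train,
            y_train,
            cofactors=cofactors,
            gmap=gmap,
            exclusion_window_cm=exclusion_window_cm,
            alpha=alpha,
        )
        sig_mask = scan["significant"].to_numpy()
        det_count += sig_mask
        sum_beta[sig_mask] += scan.loc[sig_mask, "beta"].to_numpy()
        sum_p[sig_mask] += scan.loc[sig_mask, "p_holm"].to_numpy()
        sum_r2[sig_mask] += scan.loc[sig_mask, "r2"].to_numpy()

        sig_markers = tuple(scan.loc[sig_mask, "marker"])
        model = fit_joint_model(train, y_train, sig_markers)
        k = len(model.kept_marker_cols)
        n_train = len(split.training_idx)
        try:
            r2_adj = adjusted_r2(model.r2, n_train, k)
        except ValueError:
            r2_adj = float("nan")
        # Holdout dosages imputed with *training* family means to avoid
        # leaking holdout information.
        hold_dosage = _impute_with_training_means(train, hold)
        r2_pred = predictive_ability(model, hold, y_hold, holdout_dosage=hold_dosage)
        run_rows.append(
            {
                "run": run,
                "n_train": n_train,
                "n_holdout": len(split.holdout_idx),
                "n_cofactors": len(cofactors),
                "n_significant": int(sig_mask.sum()),
                "r2_model": model.r2,
                "r2_adj": r2_adj,
                "r2_pred": r2_pred,
            }
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_beta = np.where(det_count > 0, sum_beta / det_count, np.nan)
        mean_p = np.where(det_count > 0, sum_p / det_count, np.nan)
        mean_r2 = np.where(det_count > 0, sum_r2 / det_count, np.nan)
    marker_table = pd.DataFrame(
        {
            "marker": list(genotypes.marker_ids),
            "chromosome": list(gmap.chromosomes),
            "cm": gmap.positions_cm,
            "detection_count": det_count,
            "detection_rate": det_count / n_runs,
            "mean_beta": mean_beta,
            "mean_effect_2beta": 2.0 * mean_beta,
            "mean_p_holm": mean_p,
            "mean_r2": mean_r2,
        }
    )
    run_table = pd.DataFrame.from_records(run_rows)
    return CVResult(
        marker_table=marker_table,
        run_table=run_table,
        n_runs=n_runs,
        mean_r2_adj=float(np.nanmean(run_table["r2_adj"].to_numpy())),
        mean_r2_pred=float(np.nanmean(run_table["r2_pred"].to_numpy())),
    )


def _impute_with_training_means(
    train: GenotypeMatrix, hold: GenotypeMatrix
) -> np.ndarray:
    dosage = hold.dosage.copy()
    if not np.isnan(dosage).any():
        return dosage
    train_imputed = impute_family_mean(train)
    for fam in hold.family_names:
        rows = hold.families == fam
        fam_train = train.families == fam
        means = (
            train_imputed[fam_train].mean(axis=0)
            if fam_train.any()
            else train_imputed.mean(axis=0)
        )
        block = dosage[rows]
        nan_mask = np.isnan(block)
        block[nan_mask] = np.broadcast_to(means, block.shape)[nan_mask]
        dosage[rows] = block
    return dosage


@dataclass(frozen=True)
class QTLRecord:
    """A consolidated run of qualifying markers on one chromosome."""

    qtl_id: str
    chromosome: object
    cm_from: float
    cm_until: float
    markers: tuple
    peak_marker: str
    peak_detection_rate: float
    effect_2beta: float  # most extreme (largest |2*beta|) among member markers


def consolidate_qtl(
    cv_result: CVResult | pd.DataFrame,
    gmap: GeneticMap,
    min_detection: float = 0.10,
    merge_cm: float = 4.0,
) -> list:
    """Chain qualifying markers (< ``merge_cm`` apart, strict) into QTLs.

    Markers qualify when their detection rate is >= ``min_detection``.  The
    peak marker is the member with the smallest mean adjusted p-value (ties:
    highest detection rate, then marker id); the reported effect is the
    member mean 2*beta with the largest magnitude.
    """
    table = cv_result.marker_table if isinstance(cv_result, CVResult) else cv_result
    qualifying = table[table["detection_rate"] >= min_detection].copy()
    if qualifying.empty:
        return []
    qualifying = qualifying.sort_values(
        ["chromosome", "cm", "marker"], kind="stable"
    )

    records = []
    counter: dict = {}
    for chrom, group in qualifying.groupby("chromosome", sort=False):
        positions = group["cm"].to_numpy()
        breaks = np.flatnonzero(np.diff(positions) >= merge_cm)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks + 1, [len(group)]])
        for start, stop in zip(starts, stops):
            members = group.iloc[start:stop]
            counter[chrom] = counter.get(chrom, 0) + 1
            order = members.sort_values(
                ["mean_p_holm", "detection_rate", "marker"],
                ascending=[True, False, True],
                kind="stable",
            )
            peak = order.iloc[0]
            effects = members["mean_effect_2beta"].to_numpy(dtype=float)
            extreme = effects[np.nanargmax(np.abs(effects))] if len(effects) else np.nan
            records.append(
                QTLRecord(
                    qtl_id=f"QTL-{chrom}-{counter[chrom]}",
                    chromosome=chrom,
                    cm_from=float(members["cm"].min()),
                    cm_until=float(members["cm"].max()),
                    markers=tuple(members["marker"]),
                    peak_marker=str(peak["marker"]),
                    peak_detection_rate=float(peak["detection_rate"]),
                    effect_2beta=float(extreme),
                )
            )
    return records


def combine_marker_tables(tables_by_trait: dict) -> pd.DataFrame:
    """Union view over per-trait CV marker tables for joint consolidation.

    Per marker: the maximum detection rate, the minimum mean adjusted
    p-value, and the most extreme mean 2*beta across traits.
    """
    tables = {
        trait: (t.marker_table if isinstance(t, CVResult) else t)
        for trait, t in tables_by_trait.items()
    }
    first = next(iter(tables.values()))
    out = first[["marker", "chromosome", "cm"]].copy()
    rates = np.column_stack([t["detection_rate"].to_numpy() for t in tables.values()])
    pvals = np.column_stack(
        [t["mean_p_holm"].to_numpy(dtype=float) for t in tables.values()]
    )
    effects = np.column_stack(
        [t["mean_effect_2beta"].to_numpy(dtype=float) for t in tables.values()]
    )
    out["detection_rate"] = rates.max(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["mean_p_holm"] = np.nanmin(pvals, axis=1)
        extreme_idx = np.nanargmax(
            np.where(np.isnan(effects), -np.inf, np.abs(effects)), axis=1
        )
    out["mean_effect_2beta"] = effects[np.arange(len(out)), extreme_idx]
    out["mean_beta"] = out["mean_effect_2beta"] / 2.0
    return out


def qtl_summary_table(
    qtl_records,
    cv_results_by_trait: dict,
    reference_trait: str,
    min_detection: float = 0.10,
) -> pd.DataFrame:
    """Multi-trait QTL table: one row per QTL, one effect column per trait.

    For each trait, the reported effect is the most extreme mean 2*beta among
    that trait's qualifying markers inside the QTL interval; traits without a
    qualifying marker there get a blank (NaN) cell.  The peak marker is taken
    from the reference trait's statistics within the interval.
    """
    if reference_trait not in cv_results_by_trait:
        raise ConfigurationError(
            f"reference trait {reference_trait!r} has no CV results"
        )
    tables = {
        trait: (t.marker_table if isinstance(t, CVResult) else t)
        for trait, t in cv_results_by_trait.items()
    }
    rows = []
    for record in qtl_records:
        row = {
            "qtl": record.qtl_id,
            "chromosome": record.chromosome,
            "peak_marker": record.peak_marker,
            "cm_from": record.cm_from,
            "cm_until": record.cm_until,
        }
        ref_table = tables[reference_trait]
        in_interval = (
            (ref_table["chromosome"] == record.chromosome)
            & (ref_table["cm"] >= record.cm_from)
            & (ref_table["cm"] <= record.cm_until)
            & (ref_table["detection_rate"] >= min_detection)
        )
        if in_interval.any():
            peak = ref_table[in_interval].sort_values(
                ["mean_p_holm", "marker"], kind="stable"
            ).iloc[0]
            row["peak_marker"] = str(peak["marker"])
        for trait, table in tables.items():
            hits = table[
                (table["chromosome"] == record.chromosome)
                & (table["cm"] >= record.cm_from)
                & (table["cm"] <= record.cm_until)
                & (table["detection_rate"] >= min_detection)
            ]
            effects = hits["mean_effect_2beta"].to_numpy(dtype=float)
            effects = effects[~np.isnan(effects)]
            row[f"effect_{trait}"] = (
                float(effects[np.argmax(np.abs(effects))]) if effects.size else np.nan
            )
        row["candidate_gene"] = ""
        rows.append(row)
    return pd.DataFrame.from_records(rows)
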