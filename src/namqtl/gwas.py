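"""Multi-family association scan (fixed-effects multiple regression).

Model per tested marker:

    BLUE ~ intercept + family + retained cofactors + marker dosage

Cofactors are markers chosen by greedy forward selection minimizing the
Schwarz Bayesian Criterion on the base model (intercept + family).  When a
marker is tested, cofactors on the same chromosome closer than the exclusion
window (default 1 cM, strict) — including the marker itself — are dropped
from its model.  P-values are two-sided t-tests of the dosage coefficient,
adjusted genome-wide by the Bonferroni–Holm step-down procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from namqtl.types import ConfigurationError, GeneticMap, GenotypeMatrix

__all__ = [
    "schwarz_criterion",
    "holm_adjust",
    "impute_family_mean",
    "select_cofactors",
    "scan_genome",
    "single_marker_r2",
    "family_nested_effects",
    "CofactorSet",
]

_RANK_TOL = 1e-9


def schwarz_criterion(rss: float, n: int, k: int) -> float:
    """SBC = n*ln(rss/n) + k*ln(n); k counts every estimated coefficient.

    A non-positive ``rss`` signals a perfect fit and returns -inf so that
    model comparisons short-circuit in its favour.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError("SBC requires n > k")
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + k * math.log(n)


def holm_adjust(pvalues, alpha: float = 0.05):
    """Bonferroni–Holm step-down adjustment.

    Returns ``(adjusted, significant)`` where ``significant`` flags
    ``adjusted < alpha``.  Adjusted values are monotone in the raw ordering
    and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted < alpha


def impute_family_mean(genotypes: GenotypeMatrix) -> np.ndarray:
    """Replace missing dosages with the within-family mean dosage.

    Families with no observed calls at a marker fall back to the overall
    marker mean (or 0 if the marker is entirely missing).
    """
    dosage = genotypes.dosage.copy()
    if not np.isnan(dosage).any():
        return dosage
    overall = np.nanmean(np.where(np.isnan(dosage), np.nan, dosage), axis=0)
    overall = np.nan_to_num(overall, nan=0.0)
    for fam in genotypes.family_names:
        rows = genotypes.families == fam
        block = dosage[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(block, axis=0)
        means = np.where(np.isnan(means), overall, means)
        nan_mask = np.isnan(block)
        block[nan_mask] = np.broadcast_to(means, block.shape)[nan_mask]
        dosage[rows] = block
    return dosage


def family_design(families) -> tuple[np.ndarray, list]:
    """Intercept + one-hot family contrasts (first family as reference)."""
    families = np.asarray(families, dtype=object)
    levels = list(dict.fromkeys(families))
    n = families.size
    x = np.ones((n, len(levels)))
    for j, level in enumerate(levels[1:], start=1):
        x[:, j] = (families == level).astype(float)
    return x, levels


def _ols(x: np.ndarray, y: np.ndarray):
    """Least squares fit returning (coef, rss, rank, XtX_pinv)."""
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    rss = float(resid @ resid)
    return coef, rss, rank


@dataclass(frozen=True)
class CofactorSet:
    """Markers retained as background cofactors, in selection order."""

    markers: tuple
    sbc_trajectory: tuple  # criterion after the base model, then each addition

    def __len__(self):
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)


def _align_blues(genotypes: GenotypeMatrix, blues: pd.Series) -> np.ndarray:
    if isinstance(blues, pd.Series):
        try:
            return blues.loc[list(genotypes.line_ids)].to_numpy(dtype=float)
        except KeyError as exc:
            raise ConfigurationError(f"BLUEs missing for some lines: {exc}") from exc
    arr = np.asarray(blues, dtype=float)
    if arr.size != genotypes.n_lines:
        raise ConfigurationError("BLUEs length does not match genotype lines")
    return arr


def select_cofactors(
    genotypes: GenotypeMatrix,
    blues,
    family_labels=None,
    gmap: GeneticMap | None = None,
    max_cofactors: int | None = None,
) -> CofactorSet:
    """Greedy forward selection of cofactor markers minimizing the SBC.

    The base model holds intercept + family effects; all markers compete
    simultaneously.  Selection stops when no candidate lowers the criterion.
    Ties are broken by map position (when a map is given), then marker id.
    """
    y = _align_blues(genotypes, blues)
    families = np.asarray(
        family_labels if family_labels is not None else genotypes.families,
        dtype=object,
    )
    n = y.size
    base, _ = family_design(families)
    k = base.shape[1]
    if n <= k + 1:
        raise ConfigurationError("too few lines for cofactor selection")

    # Orthonormal basis of the current model; residualize y and candidates
    # once, then update incrementally as cofactors enter.
    q0, _ = np.linalg.qr(base)
    ry = y - q0 @ (q0.T @ y)
    candidates = impute_family_mean(genotypes)
    rm = candidates - q0 @ (q0.T @ candidates)
    rss = float(ry @ ry)
    current_sbc = schwarz_criterion(rss, n, k) if rss > 0 else -math.inf

    marker_ids = genotypes.marker_ids
    positions = gmap.positions_cm if gmap is not None else None
    selected: list[int] = []
    trajectory = [current_sbc]
    available = np.ones(genotypes.n_markers, dtype=bool)

    while True:
        if max_cofactors is not None and len(selected) >= max_cofactors:
            break
        if n <= k + 1:
            break
        norms2 = np.einsum("ij,ij->j", rm, rm)
        usable = available & (norms2 > _RANK_TOL * n)
        if not usable.any():
            break
        proj = rm.T @ ry
        gains = np.zeros(genotypes.n_markers)
        gains[usable] = proj[usable] ** 2 / norms2[usable]
        new_rss = np.maximum(rss - gains, 0.0)
        with np.errstate(divide="ignore"):
            sbc = np.where(
                usable,
                np.where(
                    new_rss > 0,
                    n * np.log(new_rss / n) + (k + 1) * math.log(n),
                    -math.inf,
                ),
                math.inf,
            )
        best = float(sbc[usable].min())
        if not best < current_sbc:
            break
        tied = np.flatnonzero(usable & (sbc <= best + 1e-10))
        if positions is not None:
            tied = sorted(tied, key=lambda j: (positions[j], marker_ids[j]))
        else:
            tied = sorted(tied, key=lambda j: marker_ids[j])
        j = int(tied[0])

        qj = rm[:, j] / math.sqrt(norms2[j])
        ry = ry - qj * (qj @ ry)
        rm = rm - np.outer(qj, qj @ rm)
        rss = float(ry @ ry)
        k += 1
        selected.append(j)
        available[j] = False
        current_sbc = schwarz_criterion(rss, n, k) if rss > 0 else -math.inf
        trajectory.append(current_sbc)
        if rss <= 0:
            break

    return CofactorSet(
        markers=tuple(marker_ids[j] for j in selected),
        sbc_trajectory=tuple(trajectory),
    )


def single_marker_r2(genotypes: GenotypeMatrix, blues, marker) -> float:
    """R^2 of ``trait ~ intercept + dosage`` for one marker alone."""
    y = _align_blues(genotypes, blues)
    j = genotypes.marker_ids.index(marker) if not isinstance(marker, (int, np.integer)) else int(marker)
    dosage = impute_family_mean(genotypes)[:, j]
    if np.std(dosage) == 0:
        raise ValueError(f"marker {genotypes.marker_ids[j]!r} is monomorphic")
    x = np.column_stack([np.ones_like(y), dosage])
    _, rss, _ = _ols(x, y)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return max(0.0, 1.0 - rss / tss)


def scan_genome(
    genotypes: GenotypeMatrix,
    blues,
    family_labels=None,
    cofactors: CofactorSet | tuple = (),
    gmap: GeneticMap | None = None,
    exclusion_window_cm: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genome-wide marker scan with cofactor exclusion and Holm adjustment.

    Returns one row per marker: ``marker, chromosome, cm, tested, beta,
    effect_2beta, se, t, p_raw, p_holm, significant, r2,
    excluded_cofactors``.  Monomorphic markers are flagged untested and do
    not enter the Holm family.
    """
    if gmap is None:
        raise ConfigurationError("scan_genome requires a genetic map")
    if tuple(gmap.marker_ids) != tuple(genotypes.marker_ids):
        raise ConfigurationError("map and genotype marker order differ")
    y = _align_blues(genotypes, blues)
    families = np.asarray(
        family_labels if family_labels is not None else genotypes.families,
        dtype=object,
    )
    base, _ = family_design(families)
    dosage = impute_family_mean(genotypes)
    n = y.size

    cof_ids = tuple(cofactors)
    cof_idx = np.array([genotypes.marker_ids.index(c) for c in cof_ids], dtype=int)
    chroms = np.asarray(gmap.chromosomes, dtype=object)
    positions = gmap.positions_cm

    tss = float(((y - y.mean()) ** 2).sum())
    records = []
    for j in range(genotypes.n_markers):
        marker_dosage = dosage[:, j]
        excluded = [
            cof_ids[i]
            for i, cj in enumerate(cof_idx)
            if cj == j
            or (
                chroms[cj] == chroms[j]
                and abs(positions[cj] - positions[j]) < exclusion_window_cm
            )
        ]
        retained = [i for i, c in enumerate(cof_ids) if c not in excluded]
        row = {
            "marker": genotypes.marker_ids[j],
            "chromosome": chroms[j],
            "cm": positions[j],
            "tested": False,
            "beta": np.nan,
            "effect_2beta": np.nan,
            "se": np.nan,
            "t": np.nan,
            "p_raw": np.nan,
            "r2": np.nan,
            "excluded_cofactors": ",".join(excluded),
        }
        if np.std(marker_dosage) == 0:
            records.append(row)
            continue

        x = np.column_stack(
            [base] + [dosage[:, cof_idx[i]] for i in retained] + [marker_dosage]
        )
        coef, rss, rank = _ols(x, y)
        if rank < x.shape[1]:
            # Rank deficiency: check whether the dosage column itself is
            # collinear with the rest of the model.
            others = x[:, :-1]
            qo, _ = np.linalg.qr(others)
            resid_dosage = marker_dosage - qo @ (qo.T @ marker_dosage)
            if float(resid_dosage @ resid_dosage) <= _RANK_TOL * n:
                warnings.warn(
                    f"marker {genotypes.marker_ids[j]!r} collinear with model; "
                    "coefficient dropped",
                    stacklevel=2,
                )
                records.append(row)
                continue
            # Collinearity among cofactors only: refit on a full-rank subset.
            keep = _independent_columns(others)
            x = np.column_stack([others[:, keep], marker_dosage])
            coef, rss, rank = _ols(x, y)
        df_resid = n - rank
        if df_resid < 1:
            records.append(row)
            continue
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.pinv(x.T @ x)
        se = math.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0))
        beta = float(coef[-1])
        if se == 0:
            tstat = math.inf if beta != 0 else 0.0
            p = 0.0 if beta != 0 else 1.0
        else:
            tstat = beta / se
            p = 2.0 * scipy.stats.t.sf(abs(tstat), df_resid)
        # Single-marker R2 (marker alone, no family, no cofactors).
        xm = np.column_stack([np.ones(n), marker_dosage])
        _, rss_m, _ = _ols(xm, y)
        r2 = max(0.0, 1.0 - rss_m / tss) if tss > 0 else 0.0
        row.update(
            tested=True,
            beta=beta,
            effect_2beta=2.0 * beta,
            se=se,
            t=tstat,
            p_raw=p,
            r2=r2,
        )
        records.append(row)

    result = pd.DataFrame.from_records(records)
    result["p_holm"] = np.nan
    result["significant"] = False
    tested = result["tested"].to_numpy()
    if tested.any():
        adj, sig = holm_adjust(result.loc[tested, "p_raw"].to_numpy(), alpha=alpha)
        result.loc[tested, "p_holm"] = adj
        result.loc[tested, "significant"] = sig
    return result


def _independent_columns(x: np.ndarray) -> list:
    """Indices of a maximal linearly independent column subset (greedy QR)."""
    keep: list[int] = []
    basis = np.zeros((x.shape[0], 0))
    for j in range(x.shape[1]):
        col = x[:, j]
        resid = col - basis @ (basis.T @ col)
        norm = float(resid @ resid)
        if norm > _RANK_TOL * x.shape[0]:
            basis = np.column_stack([basis, resid / math.sqrt(norm)])
            keep.append(j)
    return keep


def family_nested_effects(
    genotypes: GenotypeMatrix, blues, family_labels=None, marker=None
) -> pd.DataFrame:
    """Per-family marker effects from a family + family-nested-dosage model.

    With a full set of family intercepts the nested-slope design is
    block-diagonal, so each family's coefficient equals its within-family
    regression of the trait on dosage.  Families where the marker does not
    segregate are reported with ``estimable=False``.
    """
    y = _align_blues(genotypes, blues)
    families = np.asarray(
        family_labels if family_labels is not None else genotypes.families,
        dtype=object,
    )
    j = genotypes.marker_ids.index(marker) if not isinstance(marker, (int, np.integer)) else int(marker)
    dosage = impute_family_mean(genotypes)[:, j]
    if np.std(dosage) == 0:
        raise ValueError(f"marker {genotypes.marker_ids[j]!r} is monomorphic")

    rows = []
    for fam in dict.fromkeys(families):
        sel = families == fam
        d = dosage[sel]
        v = y[sel]
        if sel.sum() >= 2 and np.std(d) > 0:
            sxx = float(((d - d.mean()) ** 2).sum())
            sxy = float(((d - d.mean()) * (v - v.mean())).sum())
            beta = sxy / sxx
            rows.append(
                {
                    "family": fam,
                    "n_lines": int(sel.sum()),
                    "estimable": True,
                    "beta": beta,
                    "effect_2beta": 2.0 * beta,
                }
            )
        else:
            rows.append(
                {
                    "family": fam,
                    "n_lines": int(sel.sum()),
                    "estimable": False,
                    "beta": np.nan,
                    "effect_2beta": np.nan,
                }
            )
    out = pd.DataFrame.from_records(rows)
    out.insert(0, "marker", genotypes.marker_ids[j])
    return out
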