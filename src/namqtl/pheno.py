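"""Phenotype aggregation: GDD, variance components, heritability, BLUEs.

All operations act on long-format phenotype tables with columns
``line_id, year, rep, trait, value`` (one row per plot observation).

The trait model is ``value = mu + genotype + year + genotype:year + residual``.
Variance components treat every term as random; BLUEs treat genotype as fixed
with year and genotype:year random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg
import scipy.stats

from namqtl.types import ConfigurationError, validate_phenotypes

__all__ = [
    "compute_gdd",
    "estimate_variance_components",
    "heritability",
    "compute_blues",
    "descriptive_stats",
    "trait_correlations",
    "VarianceComponents",
    "DescriptiveStats",
    "CorrelationMatrix",
]

# Dense REML is O(n_obs^3) per likelihood evaluation; refuse above this size.
_REML_MAX_OBS = 4000


def compute_gdd(
    daily_mean_temps,
    sowing_day: int,
    event_day: int,
    include_sowing_day: bool = True,
) -> float:
    """Growing degree days: cumulated daily means above 0 deg C.

    Days are 1-based indices into ``daily_mean_temps``.  The window runs from
    sowing to the event day inclusive; with ``include_sowing_day=False`` the
    sowing day itself is excluded.  Only days with a mean strictly above
    0 deg C contribute (base temperature 0).
    """
    temps = np.asarray(daily_mean_temps, dtype=float)
    if event_day < sowing_day:
        raise ValueError("event_day must not precede sowing_day")
    if sowing_day < 1 or event_day > temps.size:
        raise ValueError("day window outside the temperature series")
    start = sowing_day - 1 if include_sowing_day else sowing_day
    window = temps[start:event_day]
    return float(window[window > 0.0].sum())


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated variance components (clamped at zero where applicable)."""

    v_g: float
    v_gy: float
    v_r: float
    v_year: float
    method: str

    def __iter__(self):
        return iter((self.v_g, self.v_gy, self.v_r))


def _trait_table(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    records = validate_phenotypes(records)
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ConfigurationError(f"no records for trait {trait!r}")
    return sub


def _is_balanced(sub: pd.DataFrame) -> bool:
    counts = sub.groupby(["line_id", "year"], sort=False).size()
    lines = sub["line_id"].nunique()
    years = sub["year"].nunique()
    return len(counts) == lines * years and counts.nunique() == 1


def _anova_components(sub: pd.DataFrame) -> VarianceComponents:
    """Expected-mean-squares estimator for a balanced two-way random model.

    For balanced crossed designs these moment estimators coincide with REML
    whenever all estimates are non-negative.
    """
    g = sub["line_id"].nunique()
    y = sub["year"].nunique()
    r = len(sub) // (g * y)
    grand = sub["value"].mean()
    line_means = sub.groupby("line_id")["value"].mean()
    year_means = sub.groupby("year")["value"].mean()
    cell_means = sub.groupby(["line_id", "year"])["value"].mean()

    ss_g = y * r * ((line_means - grand) ** 2).sum()
    ss_y = g * r * ((year_means - grand) ** 2).sum()
    interaction = (
        cell_means
        - line_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - year_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_gy = r * (interaction**2).sum()
    resid = sub["value"].to_numpy() - cell_means.loc[
        list(zip(sub["line_id"], sub["year"]))
    ].to_numpy()
    ss_e = (resid**2).sum()

    ms_g = ss_g / (g - 1)
    ms_y = ss_y / (y - 1)
    ms_gy = ss_gy / ((g - 1) * (y - 1))
    if r > 1:
        ms_e = ss_e / (g * y * (r - 1))
        v_r = ms_e
        v_gy = max((ms_gy - ms_e) / r, 0.0)
    else:
        # Without replication the interaction and residual are confounded;
        # report the pooled term as residual.
        v_r = ms_gy
        v_gy = 0.0
        warnings.warn(
            "no replication: genotype-by-year and residual variances are "
            "confounded; reporting their sum as v_r",
            stacklevel=3,
        )
    v_g = max((ms_g - ms_gy) / (y * r), 0.0)
    v_year = max((ms_y - ms_gy) / (g * r), 0.0)
    return VarianceComponents(v_g, v_gy, v_r, v_year, method="anova")


def _reml_components(sub: pd.DataFrame) -> VarianceComponents:
    """Dense REML for the two-way crossed random model (small data only)."""
    n = len(sub)
    if n > _REML_MAX_OBS:
        raise ConfigurationError(
            f"REML limited to {_REML_MAX_OBS} observations (got {n}); "
            "use a balanced design or method='anova'"
        )
    y_vec = sub["value"].to_numpy(dtype=float)
    lines = pd.Categorical(sub["line_id"])
    years = pd.Categorical(sub["year"])
    cells = pd.Categorical(list(zip(lines, years)))

    def indicator(codes, k):
        z = np.zeros((n, k))
        z[np.arange(n), codes] = 1.0
        return z

    z_g = indicator(lines.codes, len(lines.categories))
    z_y = indicator(years.codes, len(years.categories))
    z_gy = indicator(cells.codes, len(cells.categories))
    gram = [z @ z.T for z in (z_g, z_y, z_gy)]
    x = np.ones((n, 1))

    def neg_restricted_ll(log_params):
        vg, vy, vgy, vr = np.exp(log_params)
        v = vg * gram[0] + vy * gram[1] + vgy * gram[2] + vr * np.eye(n)
        try:
            c, low = scipy.linalg.cho_factor(v, check_finite=False)
        except scipy.linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vinv_x = scipy.linalg.cho_solve((c, low), x, check_finite=False)
        vinv_y = scipy.linalg.cho_solve((c, low), y_vec, check_finite=False)
        xtvx = x.T @ vinv_x
        beta = np.linalg.solve(xtvx, x.T @ vinv_y)
        resid = y_vec - (x @ beta).ravel()
        quad = resid @ scipy.linalg.cho_solve((c, low), resid, check_finite=False)
        return 0.5 * (logdet_v + np.linalg.slogdet(xtvx)[1] + quad)

    var0 = max(np.var(y_vec), 1e-6)
    x0 = np.log(np.full(4, var0 / 4.0))
    res = scipy.optimize.minimize(
        neg_restricted_ll, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
    )
    vg, vy, vgy, vr = np.exp(res.x)
    tiny = 1e-8 * var0
    return VarianceComponents(
        v_g=0.0 if vg < tiny else float(vg),
        v_gy=0.0 if vgy < tiny else float(vgy),
        v_r=float(vr),
        v_year=0.0 if vy < tiny else float(vy),
        method="reml",
    )


def estimate_variance_components(
    records: pd.DataFrame, trait: str, method: str = "auto"
) -> VarianceComponents:
    """Estimate (v_g, v_gy, v_r) treating all model terms as random.

    ``method='auto'`` uses the exact ANOVA estimator for balanced designs and
    dense REML otherwise.  A single year leaves v_gy inestimable and raises.
    """
    sub = _trait_table(records, trait)
    if sub["year"].nunique() < 2:
        raise ConfigurationError(
            "genotype-by-year variance requires >= 2 years of data"
        )
    if sub.groupby("line_id").size().min() < 2:
        raise ConfigurationError("every line needs >= 2 observations")
    if method == "auto":
        method = "anova" if _is_balanced(sub) else "reml"
    if method == "anova":
        if not _is_balanced(sub):
            raise ConfigurationError("ANOVA estimator requires a balanced design")
        return _anova_components(sub)
    if method == "reml":
        return _reml_components(sub)
    raise ConfigurationError(f"unknown method {method!r}")


def heritability(v_g: float, v_gy: float, v_r: float, y: int, r: int) -> float:
    """Broad-sense heritability on a line-mean basis.

    h2 = v_g / (v_g + v_gy / y + v_r / (y * r))
    """
    if min(v_g, v_gy, v_r) < 0:
        raise ValueError("variance components must be >= 0")
    if y < 1 or r < 1:
        raise ValueError("y and r must be >= 1")
    denom = v_g + v_gy / y + v_r / (y * r)
    if denom == 0:
        raise ValueError("heritability undefined: all variance components are 0")
    return v_g / denom


def compute_blues(
    records: pd.DataFrame,
    trait: str,
    varcomp: VarianceComponents | None = None,
    include_replicate: bool = False,
) -> pd.Series:
    """Per-line best linear unbiased estimates (genotype fixed).

    Year and genotype-by-year enter as random effects.  For fully balanced
    data the generalized-least-squares solution reduces to the arithmetic
    line mean; unbalanced data are solved through sparse mixed-model
    equations with variance components estimated from the data (or supplied).
    An optional replicate-within-year random term is off by default.
    """
    sub = _trait_table(records, trait)
    if _is_balanced(sub) and not include_replicate:
        blues = sub.groupby("line_id", sort=True)["value"].mean()
        blues.name = trait
        return blues

    try:
        vc = varcomp if varcomp is not None else estimate_variance_components(
            records, trait
        )
        v_y, v_gy, v_r = vc.v_year, vc.v_gy, vc.v_r
    except ConfigurationError:
        # Single-year or sparse data: no estimable year structure, fall back
        # to plain per-line means (OLS on genotype indicators).
        blues = sub.groupby("line_id", sort=True)["value"].mean()
        blues.name = trait
        return blues

    y_vec = sub["value"].to_numpy(dtype=float)
    n = len(sub)
    lines = pd.Categorical(sub["line_id"])
    years = pd.Categorical(sub["year"])
    g = len(lines.categories)

    x = scipy.sparse.csr_matrix(
        (np.ones(n), (np.arange(n), lines.codes)), shape=(n, g)
    )
    z_blocks, lambdas = [], []
    v_r = max(v_r, 1e-12)
    if v_y > 0:
        z_blocks.append(
            scipy.sparse.csr_matrix(
                (np.ones(n), (np.arange(n), years.codes)),
                shape=(n, len(years.categories)),
            )
        )
        lambdas.append(v_r / v_y)
    if v_gy > 0:
        cells = pd.Categorical(list(zip(lines.codes, years.codes)))
        z_blocks.append(
            scipy.sparse.csr_matrix(
                (np.ones(n), (np.arange(n), cells.codes)),
                shape=(n, len(cells.categories)),
            )
        )
        lambdas.append(v_r / v_gy)
    if include_replicate:
        repyear = pd.Categorical(list(zip(years.codes, sub["rep"])))
        z_blocks.append(
            scipy.sparse.csr_matrix(
                (np.ones(n), (np.arange(n), repyear.codes)),
                shape=(n, len(repyear.categories)),
            )
        )
        lambdas.append(v_r / max(vc.v_r, 1e-12))

    if not z_blocks:
        blues = sub.groupby("line_id", sort=True)["value"].mean()
        blues.name = trait
        return blues

    z = scipy.sparse.hstack(z_blocks, format="csr")
    penalty = scipy.sparse.block_diag(
        [lam * scipy.sparse.identity(zb.shape[1]) for zb, lam in zip(z_blocks, lambdas)],
        format="csr",
    )
    coeff = scipy.sparse.bmat(
        [[x.T @ x, x.T @ z], [z.T @ x, z.T @ z + penalty]], format="csc"
    )
    rhs = np.concatenate([x.T @ y_vec, z.T @ y_vec])
    solution = scipy.sparse.linalg.spsolve(coeff, rhs)
    blues = pd.Series(
        solution[:g], index=pd.Index(lines.categories, name="line_id"), name=trait
    )
    return blues.sort_index()


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    range: float
    cv_pct: float


def descriptive_stats(blues: pd.Series, trait: str | None = None) -> DescriptiveStats:
    """n, mean, SD (ddof=1), min, max, range and CV% of per-line values."""
    values = np.asarray(blues, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("descriptive statistics need >= 2 lines")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if mean == 0:
        warnings.warn("mean is zero: CV%% undefined", stacklevel=2)
        cv = float("nan")
    else:
        cv = 100.0 * sd / mean
    return DescriptiveStats(
        n=int(values.size),
        mean=mean,
        sd=sd,
        min=float(values.min()),
        max=float(values.max()),
        range=float(values.max() - values.min()),
        cv_pct=cv,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float = 1e-4

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha


def trait_correlations(
    blues_table: pd.DataFrame, alpha: float = 1e-4
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between trait BLUEs.

    ``blues_table`` is lines x traits.  Pairs with fewer than 3 complete
    observations or zero variance get NaN entries (with a warning).
    """
    traits = list(blues_table.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = blues_table[traits[i]].notna().sum()
    for i in range(k):
        for j in range(i + 1, k):
            pair = blues_table[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            a = pair[traits[i]].to_numpy(dtype=float)
            b = pair[traits[j]].to_numpy(dtype=float)
            if len(pair) < 3 or a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"correlation undefined for ({traits[i]}, {traits[j]})",
                    stacklevel=2,
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            result = scipy.stats.pearsonr(a, b)
            r[i, j] = r[j, i] = result.statistic
            p[i, j] = p[j, i] = result.pvalue
    idx = pd.Index(traits)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        alpha=alpha,
    )
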