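"""Quantitative-genetic summaries from plot-level trait tables.

Breeding values are genotype means of trait values adjusted for fixed
design-row effects by least squares; broad-sense heritability is the
genotype variance component over total (genotype + residual), estimated by
an expected-mean-squares (method-of-moments) ANOVA that is exactly the
classical ``σ̂²_g = (MS_g − MS_e)/r`` for balanced data and uses the
Henderson-style effective replicate number for unbalanced data; the genetic
correlation between two traits is the Pearson correlation of their
breeding values, with a permutation p-value.  Treatments are always
analyzed separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError


@dataclass(frozen=True)
class GeneticsResult:
    """Variance components and summaries for one trait in one treatment."""

    treatment: str
    trait: str
    n_genotypes: int
    var_genotype: float
    var_residual: float
    heritability_pct: float
    breeding_values: pd.Series


def _row_effects(y: np.ndarray, genotype: np.ndarray,
                 row: np.ndarray) -> pd.Series:
    """OLS design-row effects with the first row level as reference.

    Fitted jointly with genotype dummies so unbalanced designs do not leak
    genotype differences into the row effects.  Reference-level coding
    means a constant added to a non-reference row is absorbed entirely by
    that row's effect, leaving breeding values untouched.
    """
    rows = pd.unique(row)
    if len(rows) == 1:
        return pd.Series({rows[0]: 0.0})
    g_dum = pd.get_dummies(pd.Series(genotype), dtype=float)
    r_dum = pd.get_dummies(pd.Series(row), dtype=float).iloc[:, 1:]
    X = np.hstack([g_dum.to_numpy(), r_dum.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    eff = pd.Series(0.0, index=pd.Index(rows))
    for name, b in zip(r_dum.columns, beta[g_dum.shape[1]:]):
        eff[name] = b
    return eff


def _adjusted(df: pd.DataFrame, trait: str, genotype: str,
              row: str) -> pd.Series:
    y = df[trait].to_numpy(dtype=float)
    eff = _row_effects(y, df[genotype].to_numpy(), df[row].to_numpy())
    return pd.Series(y - eff.loc[df[row]].to_numpy(), index=df.index)


def breeding_values(df: pd.DataFrame, trait: str, genotype: str = "genotype",
                    row: str = "row",
                    treatment: str | None = "treatment") -> pd.DataFrame:
    """Row-adjusted genotype trait means, split by treatment.

    Returns a DataFrame indexed by genotype with one column per treatment
    (a single ``value`` column when ``treatment`` is None).  Genotypes
    absent from a treatment carry NaN.
    """
    df = df.dropna(subset=[trait])
    if treatment is None:
        adj = _adjusted(df, trait, genotype, row)
        return adj.groupby(df[genotype]).mean().to_frame("value")
    out = {}
    for t, sub in df.groupby(treatment, sort=True):
        adj = _adjusted(sub, trait, genotype, row)
        out[t] = adj.groupby(sub[genotype]).mean()
    return pd.DataFrame(out)


def variance_components(df: pd.DataFrame, trait: str,
                        genotype: str = "genotype",
                        row: str = "row") -> tuple[float, float]:
    """EMS estimates ``(σ²_g, σ²_e)`` from a single-treatment trait table.

    One-way genotype ANOVA on row-adjusted values.  Balanced designs give
    the textbook ``σ̂²_g = (MS_g − MS_e)/r``; unbalanced ones use the
    adjusted replicate number ``r₀ = (N − Σn_i²/N)/(g − 1)``.  A negative
    genotype component is clamped to zero.
    """
    df = df.dropna(subset=[trait])
    adj = _adjusted(df, trait, genotype, row)
    groups = adj.groupby(df[genotype])
    n_i = groups.size().to_numpy(dtype=float)
    g = len(n_i)
    n_total = n_i.sum()
    if g < 2:
        raise ParameterError("need at least 2 genotypes")
    if n_total - g < 1:
        raise ParameterError("need replicated genotypes to separate "
                             "genetic and residual variance")
    grand = adj.mean()
    means = groups.mean()
    ss_between = float((n_i * (means.to_numpy() - grand) ** 2).sum())
    ss_within = float(((adj.to_numpy()
                        - means.loc[df[genotype]].to_numpy()) ** 2).sum())
    ms_g = ss_between / (g - 1)
    ms_e = ss_within / (n_total - g)
    r0 = (n_total - (n_i**2).sum() / n_total) / (g - 1)
    var_g = max((ms_g - ms_e) / r0, 0.0)
    return var_g, ms_e


def heritability(df: pd.DataFrame, trait: str, genotype: str = "genotype",
                 row: str = "row",
                 treatment: str | None = None):
    """Broad-sense heritability ``H² = 100·σ²_g/(σ²_g + σ²_e)`` in percent.

    With ``treatment`` given, returns a dict keyed by treatment level.
    """
    if treatment is not None:
        return {t: heritability(sub, trait, genotype, row)
                for t, sub in df.groupby(treatment, sort=True)}
    var_g, var_e = variance_components(df, trait, genotype, row)
    total = var_g + var_e
    if total == 0:
        return 0.0
    return 100.0 * var_g / total


def genetic_correlation(bv_trait1: pd.Series, bv_trait2: pd.Series,
                        n_permutations: int = 10000,
                        seed: int = 0) -> tuple[float, float]:
    """Pearson correlation of two traits' breeding values, plus a
    permutation p-value (two-sided, genotype labels shuffled)."""
    joined = pd.concat([bv_trait1, bv_trait2], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ParameterError("need at least 3 genotypes with both values")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("breeding values have zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = 0
    for _ in range(n_permutations):
        rp = float((xc[rng.permutation(len(xc))] * yc).sum() / denom)
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return r, p


def analyze(plot_table: pd.DataFrame,
            traits: tuple[str, str] = ("ch_mean_m", "cc_mean_pct"),
            genotype: str = "genotype", row: str = "row",
            treatment: str = "treatment",
            n_permutations: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Per-treatment genetics report for a pair of traits.

    One output row per (treatment, trait) with variance components and H²,
    plus the between-trait genetic correlation and its permutation p-value
    repeated on both rows of a treatment.
    """
    rows = []
    for t, sub in plot_table.groupby(treatment, sort=True):
        bvs = {}
        for trait in traits:
            bvs[trait] = breeding_values(sub, trait, genotype, row,
                                         treatment=None)["value"]
        r, p = genetic_correlation(bvs[traits[0]], bvs[traits[1]],
                                   n_permutations=n_permutations, seed=seed)
        for trait in traits:
            var_g, var_e = variance_components(sub.dropna(subset=[trait]),
                                               trait, genotype, row)
            h2 = 100.0 * var_g / (var_g + var_e) if var_g + var_e > 0 else 0.0
            rows.append((t, trait, bvs[trait].notna().sum(), var_g, var_e,
                         h2, r, p))
    return pd.DataFrame(rows, columns=[
        "treatment", "trait", "n_genotypes", "var_genotype", "var_residual",
        "heritability_pct", "genetic_correlation", "perm_p",
    ])
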