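"""Stage-wise negative-binomial differential expression.

Each tumor stage (T1..T4) is compared against the normal group on size-factor
normalized counts with a per-gene negative-binomial Wald test. Genes are
pre-filtered on abundance (FPKM above a class-specific threshold in at least
a minimum fraction of samples) so that the Benjamini-Hochberg correction only
counts genes that were actually tested. "Common" DE genes are those that pass
|log2FC| and FDR thresholds in all four comparisons with a consistent sign.

The test is a plain NB Wald test: group means on normalized counts, a
method-of-moments dispersion pooled across the two groups (floored at 1e-8),
a delta-method standard error for the log ratio, and a t reference with
n1+n2-2 degrees of freedom to absorb dispersion-estimation noise at small
group sizes. Shrinkage estimators and outlier filtering are deliberately out
of scope; calibration is checked by simulation instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import STAGES, ExpressionMatrix, SampleTable, estimate_size_factors

#: pseudo-count keeping fold changes finite for genes with an all-zero group
PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


def abundance_filter(em: ExpressionMatrix, threshold: float, min_fraction: float) -> list[str]:
    """Genes whose FPKM exceeds ``threshold`` in >= ceil(min_fraction * n) samples."""
    if em.unit != "fpkm":
        raise ValueError(f"abundance filter requires fpkm, got unit {em.unit!r}")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    arr = em.values.to_numpy(float)
    need = math.ceil(min_fraction * arr.shape[1])
    keep = (arr > threshold).sum(axis=1) >= need
    return [g for g, k in zip(em.gene_ids, keep) if k]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaNs pass through and do not count in m."""
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def nb_de_test(
    counts: ExpressionMatrix,
    samples: SampleTable,
    stage: str,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Normal vs one tumor stage NB Wald test.

    Returns a DataFrame indexed by gene id with columns ``base_mean``,
    ``log2fc`` (tumor vs normal), ``pvalue``, ``fdr``, ``comparison``.
    Genes with zero counts in every used sample get NA statistics and are
    excluded from the BH denominator. ``gene_ids`` optionally restricts the
    tested genes (e.g. after abundance filtering); size factors are always
    estimated from the full matrix over the used samples.
    """
    if counts.unit != "counts":
        raise ValueError(f"DE test requires counts, got unit {counts.unit!r}")
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    normal = samples.normal_ids()
    tumor = samples.tumor_ids(stage)
    if len(normal) == 0 or len(tumor) == 0:
        raise ValueError(f"comparison normal vs {stage}: a group is absent")
    if len(normal) < 3 or len(tumor) < 3:
        raise ValueError(
            f"comparison normal vs {stage}: need >=3 samples per group "
            f"(got {len(normal)} normal, {len(tumor)} tumor)"
        )
    used = normal + tumor
    sub = counts.subset_samples(used)
    sf = estimate_size_factors(sub)
    if gene_ids is not None:
        sub = sub.subset_genes(gene_ids)
    norm = sub.values.to_numpy(float) / sf.to_numpy(float)[None, :]
    n_a, n_b = len(normal), len(tumor)
    a = norm[:, :n_a]
    b = norm[:, n_a:]

    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    base_mean = norm.mean(axis=1)
    all_zero = sub.values.to_numpy(float).sum(axis=1) == 0

    log2fc = np.log2((mu_b + PSEUDOCOUNT) / (mu_a + PSEUDOCOUNT))

    # method-of-moments NB dispersion, pooled over groups, floored
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mu_a) / mu_a**2
        alpha_b = (var_b - mu_b) / mu_b**2
    alpha_a = np.nan_to_num(alpha_a, nan=0.0, posinf=0.0, neginf=0.0)
    alpha_b = np.nan_to_num(alpha_b, nan=0.0, posinf=0.0, neginf=0.0)
    w_a, w_b = n_a - 1, n_b - 1
    alpha = np.maximum((w_a * alpha_a + w_b * alpha_b) / (w_a + w_b), DISPERSION_FLOOR)

    # delta-method SE of log((mu_b + pc)/(mu_a + pc)) under NB variance mu + alpha mu^2
    se2 = (mu_a + alpha * mu_a**2) / (n_a * (mu_a + PSEUDOCOUNT) ** 2) + (
        mu_b + alpha * mu_b**2
    ) / (n_b * (mu_b + PSEUDOCOUNT) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.log((mu_b + PSEUDOCOUNT) / (mu_a + PSEUDOCOUNT)) / np.sqrt(se2)
    wald = np.where(se2 > 0, wald, 0.0)
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df=n_a + n_b - 2)

    base_mean = np.where(all_zero, np.nan, base_mean)
    log2fc = np.where(all_zero, np.nan, log2fc)
    pvalue = np.where(all_zero, np.nan, pvalue)
    fdr = bh_adjust(pvalue)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
            "comparison": stage,
        },
        index=sub.values.index.rename("gene_id"),
    )


@dataclass
class CommonDEGSet:
    """Genes significant in all four stage comparisons with a consistent sign."""

    gene_class: str
    direction: dict[str, str]  # gene_id -> 'up' | 'down'

    def __len__(self) -> int:
        return len(self.direction)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.direction

    def ids(self) -> set[str]:
        return set(self.direction)


def common_degs(
    tables: dict[str, pd.DataFrame],
    gene_class: str = "mRNA",
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
) -> CommonDEGSet:
    """Intersect the four per-stage DE tables (|log2FC| >= fc, FDR < cutoff, same sign)."""
    missing = [s for s in STAGES if s not in tables]
    if missing:
        raise ValueError(f"missing stage comparison(s): {missing}")
    direction: dict[str, str] = {}
    common: set[str] | None = None
    for s in STAGES:
        t = tables[s]
        ok = (t["log2fc"].abs() >= fc_threshold) & (t["fdr"] < fdr_threshold)
        ok &= t["log2fc"].notna() & t["fdr"].notna()
        ids = set(t.index[ok])
        common = ids if common is None else (common & ids)
    assert common is not None
    for g in sorted(common):
        signs = {np.sign(tables[s].loc[g, "log2fc"]) for s in STAGES}
        if len(signs) == 1:
            direction[g] = "up" if signs.pop() > 0 else "down"
    return CommonDEGSet(gene_class=gene_class, direction=direction)
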