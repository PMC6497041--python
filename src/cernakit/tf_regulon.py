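"""Tree-ensemble regulator importance (GENIE3-style) with a positive-correlation filter.

For each target gene an ensemble of extremely randomized regression trees
predicts the target's (standardized) expression from the expression of the
candidate transcription factors. The importance of a TF for a target is the
total training-variance reduction attributed to splits on that TF, averaged
over trees and expressed as a fraction of the target's variance — so the
importances for one target sum to at most 1.

Two choices make the score well behaved on null targets:

* no bootstrap resampling (the canonical Extra-Trees setting): the ensemble
  is then exactly invariant to permuting the sample axis, and all randomness
  comes from the random split thresholds;
* a split admission gate ``min_variance_reduction`` (default ``10 / n``
  samples, in units of target variance): a node is only split if the weighted
  variance reduction clears the gate. A spurious split on an unrelated TF
  gains ~ chi-square(1)/n of the target variance, so the default gate rejects
  it with probability ~0.998 and a pure-noise target accumulates ~0
  importance instead of the O(1) training-impurity total a fully grown
  forest would report. The flip side is resolution: cleanly separating real
  but weak regulators from the gate needs several hundred samples.

Retained regulon edges additionally require a positive Spearman correlation
between TF and target.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats
from sklearn.ensemble import ExtraTreesRegressor

logger = logging.getLogger(__name__)


@dataclass
class Regulon:
    """One TF and its retained targets with importance and Spearman rho."""

    tf_id: str
    targets: list[tuple[str, float, float]]  # (gene_id, importance, rho)

    def target_ids(self) -> list[str]:
        return [g for g, _, _ in self.targets]


def _target_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def tree_importance(
    tf_expr: pd.DataFrame,
    targets: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    min_variance_reduction: float | None = None,
) -> pd.DataFrame:
    """Importance matrix (TF x target) from randomized regression trees.

    ``tf_expr`` and ``targets`` are genes x samples DataFrames over the same
    samples. Targets whose id is in the TF list (a TF regressing on itself)
    are skipped with a warning. Deterministic for a fixed seed: each target's
    ensemble is seeded from (seed, target index).
    """
    if list(tf_expr.columns) != list(targets.columns):
        raise ValueError("TF and target matrices must share an identical sample axis")
    if tf_expr.shape[0] < 1:
        raise ValueError("need at least one TF")
    X = tf_expr.to_numpy(float).T  # samples x TFs
    tf_ids = list(tf_expr.index)
    if min_variance_reduction is None:
        min_variance_reduction = 10.0 / X.shape[0]
    out: dict[str, np.ndarray] = {}
    for j, (gid, row) in enumerate(targets.iterrows()):
        y = row.to_numpy(float)
        if gid in tf_ids:
            logger.warning("target %s is itself a TF row; skipped", gid)
            continue
        sd = y.std()
        if sd == 0:
            logger.warning("target %s has zero variance; skipped", gid)
            continue
        yz = (y - y.mean()) / sd
        est = ExtraTreesRegressor(
            n_estimators=n_trees,
            max_features=1.0,
            bootstrap=False,
            min_impurity_decrease=min_variance_reduction,
            random_state=_target_seed(seed, j),
            n_jobs=1,
        )
        est.fit(X, yz)
        imp = np.mean(
            [t.tree_.compute_feature_importances(normalize=False) for t in est.estimators_],
            axis=0,
        )
        out[gid] = imp
    return pd.DataFrame(out, index=tf_ids)


def spearman_rho(x, y) -> float:
    rho = stats.spearmanr(np.asarray(x, float), np.asarray(y, float)).statistic
    return float(rho)


def build_regulon(
    importance: pd.DataFrame,
    tf_expr: pd.DataFrame,
    targets: pd.DataFrame,
    importance_cutoff: float = 0.005,
    rho_cutoff: float = 0.03,
) -> dict[str, Regulon]:
    """Retain (TF, gene) pairs with importance > cutoff and Spearman rho > cutoff.

    The permissive default rho cutoff (0.03) encodes "any positive
    correlation"; it is exposed as a parameter.
    """
    regulons: dict[str, Regulon] = {}
    for tf in importance.index:
        kept: list[tuple[str, float, float]] = []
        for gid in importance.columns:
            imp = float(importance.loc[tf, gid])
            if imp <= importance_cutoff:
                continue
            rho = spearman_rho(tf_expr.loc[tf], targets.loc[gid])
            if rho > rho_cutoff:
                kept.append((gid, imp, rho))
        regulons[tf] = Regulon(tf_id=tf, targets=sorted(kept, key=lambda t: (-t[1], t[0])))
    return regulons


def regulon_frame(
    importance: pd.DataFrame,
    tf_expr: pd.DataFrame,
    targets: pd.DataFrame,
    importance_cutoff: float = 0.005,
    rho_cutoff: float = 0.03,
) -> pd.DataFrame:
    """Long-format table (tf, target, importance, rho, retained) for export."""
    rows = []
    for tf in importance.index:
        for gid in importance.columns:
            imp = float(importance.loc[tf, gid])
            rho = spearman_rho(tf_expr.loc[tf], targets.loc[gid])
            rows.append(
                {
                    "tf": tf,
                    "target": gid,
                    "importance": imp,
                    "rho": rho,
                    "retained": bool(imp > importance_cutoff and rho > rho_cutoff),
                }
            )
    return pd.DataFrame(rows, columns=["tf", "target", "importance", "rho", "retained"])
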