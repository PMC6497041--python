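"""ceRNA network construction.

A competing-endogenous-RNA module is a co-expressed lncRNA-mRNA pair whose
miRNA target sets overlap more than chance. The pipeline filters candidate
pairs on Pearson correlation (r > 0.8, p < 0.05 by default, on log2
normalized expression over all samples), then scores the shared-miRNA overlap
with a hypergeometric tail probability

    P = sum_{i=c}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the miRNA universe size, K the number of miRNAs targeting the
mRNA, n the number targeting the lncRNA, and c the number shared. Modules
with BH FDR < 0.05 form a lncRNA-miRNA-mRNA network with one lncRNA-miRNA
and one miRNA-mRNA edge per shared miRNA, deduplicated across modules.

The miRNA universe is the set of differentially expressed miRNAs with at
least one interaction, keeping N self-consistent without any external
annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .data_model import ExpressionMatrix, InteractionTable
from .diff_expr import CommonDEGSet, bh_adjust

logger = logging.getLogger(__name__)


def correlate_pairs(
    lnc: ExpressionMatrix,
    mrna: ExpressionMatrix,
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of every lncRNA x mRNA pair; retain strong positive pairs.

    Both matrices must be log2-normalized over the same samples in the same
    order. Retention is strict and signed: r > r_threshold and p < p_threshold
    (two-sided p from the t transform with n-2 df). Zero-variance genes are
    skipped with a warning. Returns columns lncrna_id, mrna_id, r, pvalue.
    """
    for em in (lnc, mrna):
        if em.unit != "log2norm":
            raise ValueError(f"correlation requires log2norm, got unit {em.unit!r}")
    if lnc.sample_ids != mrna.sample_ids:
        raise ValueError("lncRNA and mRNA matrices must share an identical sample axis")
    n = len(lnc.sample_ids)
    if n < 3:
        raise ValueError(f"need >=3 shared samples for correlation, got {n}")

    def _standardize(em: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
        arr = em.values.to_numpy(float)
        sd = arr.std(axis=1)
        keep = sd > 0
        dropped = [g for g, k in zip(em.gene_ids, keep) if not k]
        if dropped:
            logger.warning("skipping %d zero-variance gene(s): %s", len(dropped), dropped[:5])
        z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        return z, [g for g, k in zip(em.gene_ids, keep) if k]

    zx, lnc_ids = _standardize(lnc)
    zy, mrna_ids = _standardize(mrna)
    r = zx @ zy.T / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    keep = (r > r_threshold) & (p < p_threshold)
    li, mi = np.nonzero(keep)
    out = pd.DataFrame(
        {
            "lncrna_id": [lnc_ids[i] for i in li],
            "mrna_id": [mrna_ids[j] for j in mi],
            "r": r[li, mi],
            "pvalue": p[li, mi],
        }
    )
    return out.sort_values(["lncrna_id", "mrna_id"], ignore_index=True)


def shared_mirna_test(
    mrna_targeting: set[str], lnc_targeting: set[str], universe: set[str]
) -> tuple[int, float]:
    """Hypergeometric tail P of the shared-miRNA count, in log-gamma space.

    Returns ``(c, P)`` with c the observed overlap and P the probability of an
    overlap >= c when n of N miRNAs are drawn without replacement against a
    fixed set of K.
    """
    if not universe:
        raise ValueError("miRNA universe is empty")
    if not mrna_targeting <= universe:
        raise ValueError("mRNA-targeting miRNA set is not contained in the universe")
    if not lnc_targeting <= universe:
        raise ValueError("lncRNA-targeting miRNA set is not contained in the universe")
    N = len(universe)
    K = len(mrna_targeting)
    n = len(lnc_targeting)
    c = len(mrna_targeting & lnc_targeting)
    hi = min(K, n)
    if c > hi:  # unreachable given set arithmetic, kept as a guard
        raise ValueError("overlap exceeds min(K, n)")

    def log_comb(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    lo = max(c, K + n - N)
    terms = [
        log_comb(K, i) + log_comb(N - K, n - i) - log_comb(N, n)
        for i in range(lo, hi + 1)
    ]
    if c == 0:
        pvalue = 1.0  # tail from zero covers the whole support
    else:
        pvalue = float(np.exp(logsumexp(terms))) if terms else 0.0
    return c, min(pvalue, 1.0)


@dataclass(frozen=True)
class CeRNAModule:
    """One lncRNA-mRNA pair with its shared-miRNA evidence."""

    lncrna_id: str
    mrna_id: str
    N: int
    K: int
    n: int
    c: int
    shared_mirna_ids: frozenset[str]
    pvalue: float
    fdr: float
    r: float

    @property
    def module_id(self) -> str:
        return f"{self.lncrna_id}|{self.mrna_id}"


def build_cerna_network(
    degs: dict[str, CommonDEGSet],
    interactions: InteractionTable,
    correlations: pd.DataFrame,
    module_fdr: float = 0.05,
    min_shared: int = 1,
) -> tuple[list[CeRNAModule], nx.Graph]:
    """Score every correlation-retained pair and assemble the ceRNA network.

    ``degs`` maps gene class -> CommonDEGSet; interactions are restricted to
    DE miRNAs and DE targets, the universe is the DE miRNAs with >=1 retained
    interaction. Every retained pair gets a hypergeometric P, BH across all
    tested pairs, and modules with fdr < module_fdr and c >= min_shared are
    kept. Network edges (lncRNA-miRNA and miRNA-mRNA per shared miRNA) are
    deduplicated across modules.
    """
    de_mirnas = degs["miRNA"].ids()
    de_targets = degs["mRNA"].ids() | degs["lncRNA"].ids()
    restricted = interactions.restrict(de_mirnas, de_targets)
    universe = set(restricted.data["mirna_id"])
    if not universe:
        raise ValueError("empty miRNA universe: no DE miRNA has a retained interaction")
    targets_of = restricted.targets_of_mirnas()

    records = []
    for row in correlations.itertuples(index=False):
        k_set = targets_of.get(row.mrna_id, set())
        n_set = targets_of.get(row.lncrna_id, set())
        c, p = shared_mirna_test(k_set, n_set, universe)
        records.append(
            {
                "lncrna_id": row.lncrna_id,
                "mrna_id": row.mrna_id,
                "N": len(universe),
                "K": len(k_set),
                "n": len(n_set),
                "c": c,
                "shared": frozenset(k_set & n_set),
                "pvalue": p,
                "r": row.r,
            }
        )
    modules: list[CeRNAModule] = []
    if records:
        fdrs = bh_adjust([rec["pvalue"] for rec in records])
        for rec, fdr in zip(records, fdrs):
            if fdr < module_fdr and rec["c"] >= min_shared:
                modules.append(
                    CeRNAModule(
                        lncrna_id=rec["lncrna_id"],
                        mrna_id=rec["mrna_id"],
                        N=rec["N"],
                        K=rec["K"],
                        n=rec["n"],
                        c=rec["c"],
                        shared_mirna_ids=rec["shared"],
                        pvalue=rec["pvalue"],
                        fdr=float(fdr),
                        r=rec["r"],
                    )
                )

    net = nx.Graph()
    for mod in modules:
        net.add_node(mod.lncrna_id, node_class="lncRNA", direction=degs["lncRNA"].direction[mod.lncrna_id])
        net.add_node(mod.mrna_id, node_class="mRNA", direction=degs["mRNA"].direction[mod.mrna_id])
        for mir in sorted(mod.shared_mirna_ids):
            net.add_node(mir, node_class="miRNA", direction=degs["miRNA"].direction[mir])
            for u, v, etype in (
                (mod.lncrna_id, mir, "lncRNA-miRNA"),
                (mir, mod.mrna_id, "miRNA-mRNA"),
            ):
                if net.has_edge(u, v):
                    net.edges[u, v]["modules"].append(mod.module_id)
                else:
                    net.add_edge(u, v, edge_type=etype, modules=[mod.module_id])
    return modules, net


def degree_ranking(network: nx.Graph) -> list[tuple[str, int]]:
    """Nodes sorted by degree (descending), ties broken lexicographically."""
    return sorted(network.degree, key=lambda kv: (-kv[1], kv[0]))


def modules_to_frame(modules: list[CeRNAModule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": m.lncrna_id,
                "mrna_id": m.mrna_id,
                "N": m.N,
                "K": m.K,
                "n": m.n,
                "c": m.c,
                "shared_mirna_ids": ",".join(sorted(m.shared_mirna_ids)),
                "pvalue": m.pvalue,
                "fdr": m.fdr,
                "r": m.r,
            }
            for m in modules
        ],
        columns=["lncrna_id", "mrna_id", "N", "K", "n", "c", "shared_mirna_ids", "pvalue", "fdr", "r"],
    )


def network_to_edge_frame(network: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "source": u,
            "target": v,
            "edge_type": d["edge_type"],
            "module_id": ";".join(d["modules"]),
        }
        for u, v, d in network.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "module_id"])
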