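"""Synthetic LUAD-like cohort with planted ceRNA triplets and known truth.

The generator emulates the structure of a staged tumor/normal bulk RNA-seq
cohort: negative-binomial counts for mRNA, lncRNA and miRNA, fold changes for
a chosen set of differentially expressed (DE) genes applied consistently
across all four tumor stages, a bipartite miRNA->target interaction graph,
and exponential proportional-hazards survival for tumor samples.

Each planted ceRNA triplet consists of one lncRNA, one mRNA and a set of
shared DE miRNAs targeting both. The lncRNA/mRNA pair shares a log-normal
latent factor added to their NB means, which induces a target Pearson
correlation (``latent_corr``) on the log2 scale; the achieved correlation is
validated empirically by the test suite rather than set exactly. Survival
hazard follows the first planted triplet's standardized latent score.

All randomness flows through one ``numpy.random.Generator`` (PCG64) seeded
from ``SimulationConfig.seed``, so a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    InteractionTable,
    SampleTable,
    write_expression_matrix,
    write_gene_lengths,
    write_interactions,
    write_sample_table,
)

_LN2 = float(np.log(2.0))


@dataclass
class SimulationConfig:
    """Cohort dimensions and effect sizes.

    Sample-count defaults follow the TCGA-LUAD composition (59 normal,
    168/276/47/19 tumor samples in stages T1-T4) scaled to desk size while
    preserving the stage ordering. ``planted_log2fc`` is the tumor-vs-normal
    shift applied to every DE gene; ``latent_corr`` is the target log-scale
    co-expression of planted lncRNA-mRNA pairs.
    """

    n_normal: int = 30
    n_t1: int = 34
    n_t2: int = 55
    n_t3: int = 10
    n_t4: int = 6
    n_mrna: int = 400
    n_lncrna: int = 150
    n_mirna: int = 120
    n_de_mrna: int = 40
    n_de_lncrna: int = 20
    n_de_mirna: int = 40
    n_planted_triplets: int = 8
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.02
    latent_corr: float = 0.9
    shared_mirnas_per_triplet: int = 5
    background_edge_prob: float = 0.01
    survival_beta: float = 0.8
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_normal": self.n_normal, "n_t1": self.n_t1, "n_t2": self.n_t2,
            "n_t3": self.n_t3, "n_t4": self.n_t4, "n_mrna": self.n_mrna,
            "n_lncrna": self.n_lncrna, "n_mirna": self.n_mirna,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_planted_triplets < 0:
            raise ValueError("n_planted_triplets must be >= 0")
        if not 0.0 < self.latent_corr < 1.0:
            raise ValueError("latent_corr must lie strictly in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_planted_triplets > min(self.n_de_lncrna, self.n_de_mrna):
            raise ValueError(
                "n_planted_triplets exceeds the DE genes available per class "
                f"({self.n_planted_triplets} > min({self.n_de_lncrna}, {self.n_de_mrna}))"
            )
        if self.n_de_mrna > self.n_mrna or self.n_de_lncrna > self.n_lncrna or self.n_de_mirna > self.n_mirna:
            raise ValueError("DE gene count exceeds gene count for some class")
        if self.n_planted_triplets > 0 and self.shared_mirnas_per_triplet > self.n_de_mirna:
            raise ValueError("shared_mirnas_per_triplet exceeds the DE miRNA pool")

    @property
    def n_tumor(self) -> int:
        return self.n_t1 + self.n_t2 + self.n_t3 + self.n_t4


@dataclass
class PlantedTriplet:
    lncrna_id: str
    mrna_id: str
    shared_mirna_ids: frozenset[str]


@dataclass
class GroundTruth:
    """What was planted: triplets, DE genes with direction, survival effects.

    ``module_scores`` holds the standardized latent score of each planted
    triplet over tumor samples — the covariate the survival times were
    actually generated from.
    """

    planted_triplets: list[PlantedTriplet]
    de_genes: dict[str, dict[str, str]]  # gene class -> {gene_id: 'up'|'down'}
    survival_beta: np.ndarray
    module_scores: pd.DataFrame

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(t.lncrna_id, t.mrna_id) for t in self.planted_triplets}


@dataclass
class Cohort:
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    samples: SampleTable
    gene_lengths: pd.Series
    interactions: InteractionTable
    ground_truth: GroundTruth

    def expression(self, gene_class: str) -> ExpressionMatrix:
        return {"mRNA": self.mrna, "lncRNA": self.lncrna, "miRNA": self.mirna}[gene_class]


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate counts, metadata, lengths, interactions and ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- samples ---------------------------------------------------------
    normal_ids = [f"NORM{i:03d}" for i in range(1, cfg.n_normal + 1)]
    stages = (["T1"] * cfg.n_t1 + ["T2"] * cfg.n_t2 + ["T3"] * cfg.n_t3 + ["T4"] * cfg.n_t4)
    tumor_ids = [f"TUM{i:03d}" for i in range(1, cfg.n_tumor + 1)]
    sample_ids = normal_ids + tumor_ids
    is_tumor = np.array([0] * cfg.n_normal + [1] * cfg.n_tumor, dtype=float)
    n_samples = len(sample_ids)

    # --- genes -----------------------------------------------------------
    ids = {
        "mRNA": [f"MRNA{i:04d}" for i in range(1, cfg.n_mrna + 1)],
        "lncRNA": [f"LNC{i:04d}" for i in range(1, cfg.n_lncrna + 1)],
        "miRNA": [f"MIR{i:04d}" for i in range(1, cfg.n_mirna + 1)],
    }
    n_genes = {"mRNA": cfg.n_mrna, "lncRNA": cfg.n_lncrna, "miRNA": cfg.n_mirna}
    base_log2 = {
        "mRNA": rng.uniform(3.0, 11.0, cfg.n_mrna),
        "lncRNA": rng.uniform(3.0, 11.0, cfg.n_lncrna),
        "miRNA": rng.uniform(4.0, 11.0, cfg.n_mirna),
    }
    lengths = pd.concat([
        pd.Series(rng.integers(500, 5001, cfg.n_mrna), index=ids["mRNA"]),
        pd.Series(rng.integers(300, 3001, cfg.n_lncrna), index=ids["lncRNA"]),
        pd.Series(rng.integers(60, 121, cfg.n_mirna), index=ids["miRNA"]),
    ]).rename("length")

    # --- DE genes and planted triplets -----------------------------------
    n_de = {"mRNA": cfg.n_de_mrna, "lncRNA": cfg.n_de_lncrna, "miRNA": cfg.n_de_mirna}
    de_idx = {c: rng.choice(n_genes[c], size=n_de[c], replace=False) for c in ids}
    direction = {c: rng.choice([-1.0, 1.0], size=n_de[c]) for c in ids}

    n_pl = cfg.n_planted_triplets
    # planted lncRNA/mRNA: first n_pl of each class's DE draw, with matched
    # direction per pair (co-expression requires a common condition shift)
    for t in range(n_pl):
        direction["mRNA"][t] = direction["lncRNA"][t]
    # planted genes sit in the well-measured expression range
    for c in ("mRNA", "lncRNA"):
        base_log2[c][de_idx[c][:n_pl]] = rng.uniform(9.0, 11.0, n_pl)
    base_log2["miRNA"][de_idx["miRNA"]] = np.maximum(base_log2["miRNA"][de_idx["miRNA"]], 6.0)

    de_genes = {
        c: {
            ids[c][g]: ("up" if d > 0 else "down")
            for g, d in zip(de_idx[c], direction[c])
        }
        for c in ids
    }
    de_mirna_ids = [ids["miRNA"][g] for g in de_idx["miRNA"]]

    triplets: list[PlantedTriplet] = []
    for t in range(n_pl):
        shared = rng.choice(de_mirna_ids, size=cfg.shared_mirnas_per_triplet, replace=False)
        triplets.append(
            PlantedTriplet(
                lncrna_id=ids["lncRNA"][de_idx["lncRNA"][t]],
                mrna_id=ids["mRNA"][de_idx["mRNA"][t]],
                shared_mirna_ids=frozenset(shared),
            )
        )

    # --- latent co-expression factors ------------------------------------
    # Var(log X) ~ dispersion + 1/mu for NB; scale the latent variance so that
    # latent/(latent+noise) hits latent_corr for the noisier pair member.
    latent = np.zeros((n_pl, n_samples))
    latent_sigma2 = np.zeros(n_pl)
    for t in range(n_pl):
        mus = []
        for c, gi in (("lncRNA", de_idx["lncRNA"][t]), ("mRNA", de_idx["mRNA"][t])):
            mu_base = 2.0 ** base_log2[c][gi]
            mu_shift = mu_base * 2.0 ** (direction[c][t] * cfg.planted_log2fc)
            mus.append(min(mu_base, mu_shift))
        v_noise = cfg.nb_dispersion + 1.0 / min(mus)
        latent_sigma2[t] = v_noise * cfg.latent_corr / (1.0 - cfg.latent_corr)
        latent[t] = rng.normal(0.0, np.sqrt(latent_sigma2[t]), n_samples)

    # --- per-sample sequencing depth --------------------------------------
    depth_log2 = rng.normal(0.0, 0.2, n_samples)

    # --- counts ------------------------------------------------------------
    matrices: dict[str, ExpressionMatrix] = {}
    for c in ("mRNA", "lncRNA", "miRNA"):
        log2_mu = np.tile(base_log2[c][:, None], (1, n_samples))
        for g, d in zip(de_idx[c], direction[c]):
            log2_mu[g] += d * cfg.planted_log2fc * is_tumor
        if c in ("mRNA", "lncRNA"):
            key = "lncRNA" if c == "lncRNA" else "mRNA"
            for t in range(n_pl):
                g = de_idx[key][t]
                log2_mu[g] += (latent[t] - latent_sigma2[t] / 2.0) / _LN2
        log2_mu += depth_log2[None, :]
        counts = _draw_nb(rng, 2.0 ** log2_mu, cfg.nb_dispersion)
        matrices[c] = ExpressionMatrix(
            pd.DataFrame(counts.astype(float), index=ids[c], columns=sample_ids),
            gene_class=c,
            unit="counts",
        )

    # --- interactions -------------------------------------------------------
    target_ids = ids["mRNA"] + ids["lncRNA"]
    target_class = ["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lncrna
    edge_mask = rng.random((cfg.n_mirna, len(target_ids))) < cfg.background_edge_prob
    rows = [
        (ids["miRNA"][m], target_ids[t], target_class[t], "simulated")
        for m, t in zip(*np.nonzero(edge_mask))
    ]
    for trip in triplets:
        for m in sorted(trip.shared_mirna_ids):
            rows.append((m, trip.lncrna_id, "lncRNA", "simulated"))
            rows.append((m, trip.mrna_id, "mRNA", "simulated"))
    inter = InteractionTable(
        pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class", "source"])
    )

    # --- survival ------------------------------------------------------------
    betas = np.zeros(n_pl)
    if n_pl > 0:
        betas[0] = cfg.survival_beta
    tumor_latent = latent[:, cfg.n_normal:]
    if n_pl > 0:
        z = (tumor_latent - tumor_latent.mean(axis=1, keepdims=True)) / tumor_latent.std(axis=1, keepdims=True)
        module_scores = pd.DataFrame(
            z.T, index=tumor_ids, columns=[f"module{t}" for t in range(n_pl)]
        )
        linpred = z.T @ betas
    else:
        module_scores = pd.DataFrame(index=tumor_ids)
        linpred = np.zeros(cfg.n_tumor)
    hazard = cfg.baseline_hazard * np.exp(linpred)
    raw_times = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        cutoff = np.quantile(raw_times, 1.0 - cfg.censor_rate)
        os_event = (raw_times <= cutoff).astype(int)
        os_time = np.minimum(raw_times, cutoff)
    else:
        os_event = np.ones(cfg.n_tumor, dtype=int)
        os_time = raw_times
    os_time = np.maximum(np.round(os_time), 1.0)  # day resolution, ties expected

    samples = SampleTable(
        pd.DataFrame(
            {
                "condition": ["normal"] * cfg.n_normal + ["tumor"] * cfg.n_tumor,
                "stage": [np.nan] * cfg.n_normal + stages,
                "os_time": [np.nan] * cfg.n_normal + list(os_time),
                "os_event": [np.nan] * cfg.n_normal + list(os_event.astype(float)),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    gt = GroundTruth(
        planted_triplets=triplets,
        de_genes=de_genes,
        survival_beta=betas,
        module_scores=module_scores,
    )
    return Cohort(
        mrna=matrices["mRNA"],
        lncrna=matrices["lncRNA"],
        mirna=matrices["miRNA"],
        samples=samples,
        gene_lengths=lengths,
        interactions=inter,
        ground_truth=gt,
    )


def truth_report(gt: GroundTruth, modules) -> tuple[float, float]:
    """Sensitivity and false-discovery proportion of reported lncRNA-mRNA pairs.

    ``modules`` is any iterable of objects with ``lncrna_id``/``mrna_id``
    attributes (or (lncrna_id, mrna_id) tuples). Sensitivity is the fraction
    of planted pairs recovered; FDP is the fraction of reported pairs that
    were not planted (0 when nothing is reported).
    """
    planted = gt.planted_pairs()
    reported: set[tuple[str, str]] = set()
    for m in modules:
        if hasattr(m, "lncrna_id"):
            reported.add((m.lncrna_id, m.mrna_id))
        else:
            lnc, mr = m
            reported.add((lnc, mr))
    sensitivity = 1.0 if not planted else len(planted & reported) / len(planted)
    fdp = 0.0 if not reported else len(reported - planted) / len(reported)
    return sensitivity, fdp


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the five input TSVs plus ground_truth.tsv to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(cohort.mrna, out / "counts_mrna.tsv")
    write_expression_matrix(cohort.lncrna, out / "counts_lncrna.tsv")
    write_expression_matrix(cohort.mirna, out / "counts_mirna.tsv")
    write_sample_table(cohort.samples, out / "samples.tsv")
    write_gene_lengths(cohort.gene_lengths, out / "gene_lengths.tsv")
    write_interactions(cohort.interactions, out / "interactions.tsv")
    rows = []
    for i, t in enumerate(cohort.ground_truth.planted_triplets):
        rows.append(
            {
                "module": f"module{i}",
                "lncrna_id": t.lncrna_id,
                "mrna_id": t.mrna_id,
                "shared_mirna_ids": ",".join(sorted(t.shared_mirna_ids)),
                "survival_beta": cohort.ground_truth.survival_beta[i],
            }
        )
    pd.DataFrame(
        rows, columns=["module", "lncrna_id", "mrna_id", "shared_mirna_ids", "survival_beta"]
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
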