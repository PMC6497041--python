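"""Core containers, TSV I/O, and count normalization.

Every stage of the pipeline works on three containers: an
:class:`ExpressionMatrix` (genes x samples, tagged with a gene class and a
unit), a :class:`SampleTable` (condition, tumor stage, overall survival), and
an :class:`InteractionTable` (directed miRNA -> target edges, as produced by
target databases such as starBase or miRTarBase).

On-disk format is a single dialect everywhere: UTF-8 tab-separated text with a
header row. Expression matrices store gene ids in the first column and sample
ids in the header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_CLASSES = ("mRNA", "lncRNA", "miRNA")
UNITS = ("counts", "fpkm", "log2norm")
STAGES = ("T1", "T2", "T3", "T4")
CONDITIONS = ("normal", "tumor")

SAMPLE_COLUMNS = ["sample_id", "condition", "stage", "os_time", "os_event"]
INTERACTION_COLUMNS = ["mirna_id", "target_id", "target_class", "source"]


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for it in items:
        if it in seen:
            dups.add(it)
        seen.add(it)
    return sorted(dups)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with class and unit tags.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    gene_class
        One of ``mRNA``, ``lncRNA``, ``miRNA``.
    unit
        One of ``counts``, ``fpkm``, ``log2norm``. Counts and FPKM must be
        finite and nonnegative.
    """

    values: pd.DataFrame
    gene_class: str
    unit: str

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}; expected one of {GENE_CLASSES}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        dup_g = _find_duplicates(self.values.index)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_s = _find_duplicates(self.values.columns)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric cells")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if self.unit in ("counts", "fpkm") and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative {self.unit} value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        self.values.index.name = "gene_id"
        self.values.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.gene_class, self.unit)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.gene_class, self.unit)


@dataclass
class SampleTable:
    """Per-sample metadata: condition, tumor stage, overall survival.

    ``data`` is indexed by sample id with columns ``condition``, ``stage``,
    ``os_time`` (days), ``os_event`` (1 = death observed, 0 = censored).
    Normal samples carry no stage and need not carry survival data; every
    tumor sample must have a stage in T1..T4.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup = _find_duplicates(df.index)
        if dup:
            raise ValueError(f"duplicate sample ids: {dup}")
        for col in ("condition", "stage", "os_time", "os_event"):
            if col not in df.columns:
                raise ValueError(f"sample table missing column {col!r}")
        bad_cond = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValueError(f"unknown condition token(s): {bad_cond}")
        is_tumor = df["condition"] == "tumor"
        stage = df["stage"]
        missing = df.index[is_tumor & stage.isna()]
        if len(missing):
            raise ValueError(f"tumor sample(s) missing stage: {sorted(missing)}")
        bad_stage = sorted(set(stage[is_tumor]) - set(STAGES))
        if bad_stage:
            raise ValueError(f"unknown stage token(s): {bad_stage}")
        staged_normal = df.index[~is_tumor & stage.notna()]
        if len(staged_normal):
            raise ValueError(f"normal sample(s) must not carry a stage: {sorted(staged_normal)}")
        t = df["os_time"]
        if (t.dropna() <= 0).any():
            raise ValueError("os_time must be positive where present")
        ev = df["os_event"].dropna()
        if not set(ev.astype(float)) <= {0.0, 1.0}:
            raise ValueError("os_event must be 0 or 1 where present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def normal_ids(self) -> list[str]:
        return list(self.data.index[self.data["condition"] == "normal"])

    def tumor_ids(self, stage: str | None = None) -> list[str]:
        mask = self.data["condition"] == "tumor"
        if stage is not None:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            mask &= self.data["stage"] == stage
        return list(self.data.index[mask])

    def survival(self, sample_ids: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, events) for the given samples (default: all tumor)."""
        ids = self.tumor_ids() if sample_ids is None else list(sample_ids)
        sub = self.data.loc[ids]
        if sub["os_time"].isna().any() or sub["os_event"].isna().any():
            missing = sorted(sub.index[sub["os_time"].isna() | sub["os_event"].isna()])
            raise ValueError(f"samples lack survival data: {missing}")
        return sub["os_time"].to_numpy(float), sub["os_event"].to_numpy(float).astype(int)


@dataclass
class InteractionTable:
    """Directed miRNA -> target edges with the target's gene class.

    Duplicate (mirna_id, target_id) rows are dropped at construction with a
    logged count; the class of a target must be consistent across rows.
    """

    data: pd.DataFrame
    n_deduplicated: int = field(default=0)

    def __post_init__(self) -> None:
        df = self.data
        for col in INTERACTION_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"interaction table missing column {col!r}")
        before = len(df)
        df = df.drop_duplicates(subset=["mirna_id", "target_id"], keep="first").reset_index(drop=True)
        dropped = before - len(df)
        if dropped:
            logger.info("deduplicated %d interaction row(s)", dropped)
        self.n_deduplicated = dropped
        bad_class = sorted(set(df["target_class"]) - {"mRNA", "lncRNA"})
        if bad_class:
            raise ValueError(f"unknown target_class token(s): {bad_class}")
        per_target = df.groupby("target_id")["target_class"].nunique()
        inconsistent = sorted(per_target.index[per_target > 1])
        if inconsistent:
            raise ValueError(f"target(s) with inconsistent class: {inconsistent}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def targets_of_mirnas(self) -> dict[str, set[str]]:
        """Map target_id -> set of miRNAs targeting it."""
        out: dict[str, set[str]] = {}
        for m, t in zip(self.data["mirna_id"], self.data["target_id"]):
            out.setdefault(t, set()).add(m)
        return out

    def restrict(self, mirnas: set[str], targets: set[str]) -> "InteractionTable":
        df = self.data
        keep = df["mirna_id"].isin(mirnas) & df["target_id"].isin(targets)
        return InteractionTable(df[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, gene_class: str, unit: str) -> ExpressionMatrix:
    """Read a `gene_id<TAB>S1<TAB>S2...` matrix, preserving input order.

    Duplicate gene or sample ids and non-numeric cells are hard errors naming
    the offending id or cell.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup_s = _find_duplicates(header[1:])
    if dup_s:
        raise ValueError(f"duplicate sample ids in {path}: {dup_s}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = header[1:]
    dup_g = _find_duplicates(df.index)
    if dup_g:
        raise ValueError(f"duplicate gene ids in {path}: {dup_g}")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at gene {df.index[g]!r}, sample {df.columns[s]!r}: {df.iat[g, s]!r}"
        )
    if num.isna().to_numpy().any():
        g, s = np.argwhere(num.isna().to_numpy())[0]
        raise ValueError(f"empty cell in {path} at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    return ExpressionMatrix(num.astype(float), gene_class, unit)


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str, "stage": str})
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"sample table {path} missing column {col!r}")
    df = df.set_index("sample_id")
    df["stage"] = df["stage"].replace("", np.nan)
    df["os_time"] = pd.to_numeric(df["os_time"], errors="raise")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="raise")
    return SampleTable(df[["condition", "stage", "os_time", "os_event"]])


def write_sample_table(st: SampleTable, path) -> None:
    st.data.to_csv(path, sep="\t", index_label="sample_id")


def read_interactions(path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return InteractionTable(df[INTERACTION_COLUMNS].copy())


def write_interactions(it: InteractionTable, path) -> None:
    it.data.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "length" not in df.columns:
        raise ValueError(f"gene length table {path} must have columns gene_id, length")
    lengths = pd.to_numeric(df.set_index("gene_id")["length"], errors="raise")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1")
    return lengths.astype(int)


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(em: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (DESeq convention), geometric mean 1.

    The reference for each gene is its geometric mean across samples; only
    genes with strictly positive counts in every sample contribute. The
    resulting factors are rescaled to geometric mean 1.
    """
    if em.unit != "counts":
        raise ValueError(f"size factors require counts, got unit {em.unit!r}")
    arr = em.values.to_numpy(float)
    if arr.shape[1] < 2:
        raise ValueError("size factors require at least 2 samples")
    zero_free = (arr > 0).all(axis=1)
    if not zero_free.any():
        raise ValueError(
            "no gene with positive counts in every sample; "
            "pseudo-reference fallback is not applied"
        )
    logc = np.log(arr[zero_free])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # enforce geometric mean exactly 1
    return pd.Series(np.exp(log_sf), index=em.values.columns, name="size_factor")


def compute_fpkm(em: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """FPKM: counts * 1e9 / (gene length [bp] * per-sample total counts)."""
    if em.unit != "counts":
        raise ValueError(f"FPKM requires counts, got unit {em.unit!r}")
    missing = [g for g in em.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene length(s): {missing[:10]}")
    arr = em.values.to_numpy(float)
    totals = arr.sum(axis=0)
    if (totals <= 0).any():
        bad = [em.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"sample(s) with zero total counts: {bad}")
    lens = lengths.loc[em.gene_ids].to_numpy(float)
    fpkm = arr * 1e9 / (lens[:, None] * totals[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=em.values.index, columns=em.values.columns),
        em.gene_class,
        "fpkm",
    )


def log2_normalize(em: ExpressionMatrix, size_factors: pd.Series | None = None) -> ExpressionMatrix:
    """log2(counts / size_factor + 1); factors estimated if not given."""
    if em.unit != "counts":
        raise ValueError(f"log2 normalization requires counts, got unit {em.unit!r}")
    sf = estimate_size_factors(em) if size_factors is None else size_factors
    norm = em.values.to_numpy(float) / sf.loc[em.sample_ids].to_numpy(float)[None, :]
    return ExpressionMatrix(
        pd.DataFrame(np.log2(norm + 1.0), index=em.values.index, columns=em.values.columns),
        em.gene_class,
        "log2norm",
    )
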