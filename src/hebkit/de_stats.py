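"""Count normalisation and Fisher's-exact differential expression.

The differential-expression substrate used by every downstream classifier:
a :class:`CountMatrix` container for gene x sample read counts, RPKM
normalisation, a two-sided Fisher's exact test on pooled group counts
against pooled library sizes, Benjamini-Hochberg FDR, and the trichotomous
up / down / ns call at FDR <= 0.05 and fold change > 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "filter_expressed",
    "rpkm",
    "fisher_de",
    "fisher_de_many",
    "bh_fdr",
    "call_de",
    "DE_ALPHA",
    "LOG2FC_MIN",
]

#: FDR threshold for a differential-expression call.
DE_ALPHA = 0.05
#: |log2 fold change| that must be exceeded ("fold change > 2").
LOG2FC_MIN = 1.0
#: pseudocount added to pooled counts for fold-change only, never for the test.
PSEUDOCOUNT = 0.5

# relative tolerance when comparing hypergeometric point probabilities;
# the convention of standard exact-test implementations.
_PG_RELTOL = 1e-7


@dataclass
class CountMatrix:
    """Raw read counts per gene per sample with the metadata DE needs.

    Parameters
    ----------
    counts
        Integer DataFrame, genes as rows, samples as columns.
    lengths
        Exon length in bp per gene (Series indexed like ``counts``).
    library_sizes
        Total mapped reads per sample.  May exceed the column sum: it is
        the library's total mapped reads, not the sum over analysed genes.
    groups
        Mapping sample id -> group label (e.g. R, C, F1, F18).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.lengths = pd.Series(self.lengths, dtype=float).reindex(self.counts.index)
        self.library_sizes = pd.Series(self.library_sizes, dtype=float).reindex(
            self.counts.columns
        )
        self.groups = pd.Series(self.groups).reindex(self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
            raise ValueError("every sample needs a positive library size")
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def group_samples(self, group: str) -> list[str]:
        out = [s for s in self.samples if self.groups[s] == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out

    def pooled_counts(self, group: str) -> pd.Series:
        """Replicate counts summed per gene for one group."""
        return self.counts[self.group_samples(group)].sum(axis=1)

    def pooled_library_size(self, group: str) -> float:
        return float(self.library_sizes[self.group_samples(group)].sum())

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        idx = self.counts.index.intersection(pd.Index(genes))
        return CountMatrix(
            self.counts.loc[idx], self.lengths.loc[idx], self.library_sizes, self.groups
        )

    def reads_per_million(self, sample: str) -> pd.Series:
        """Per-gene reads per million mapped reads of one library."""
        return self.counts[sample] * 1e6 / self.library_sizes[sample]

    # -- I/O ---------------------------------------------------------------
    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.rename_axis("gene").to_csv(outdir / "counts.tsv", sep="\t")
        self.lengths.rename("length_bp").rename_axis("gene").to_csv(
            outdir / "lengths.tsv", sep="\t"
        )
        meta = pd.DataFrame(
            {"group": self.groups, "library_size": self.library_sizes.astype(np.int64)}
        )
        meta.rename_axis("sample").to_csv(outdir / "samples.tsv", sep="\t")

    @classmethod
    def from_dir(cls, indir: str | Path) -> "CountMatrix":
        indir = Path(indir)
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
        lengths = pd.read_csv(indir / "lengths.tsv", sep="\t", index_col=0)["length_bp"]
        meta = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
        return cls(counts, lengths, meta["library_size"], meta["group"])

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        lengths_path: str | Path,
        samples_path: str | Path,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        meta = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts, lengths, meta["library_size"], meta["group"])


def filter_expressed(
    cm: CountMatrix, groups: Sequence[str] | None = None
) -> tuple[CountMatrix, int]:
    """Keep genes with count >= 1 in *all* biological replicates.

    The prefilter removes expression noise before any DE analysis: a gene
    must have at least one read in every replicate of every group under
    analysis.  Returns the filtered matrix and the number of genes removed.
    """
    if groups is None:
        groups = list(dict.fromkeys(cm.groups))
    samples = [s for s in cm.samples if cm.groups[s] in set(groups)]
    if not samples:
        raise ValueError(f"no samples in groups {groups!r}")
    keep = (cm.counts[samples] >= 1).all(axis=1)
    removed = int((~keep).sum())
    if keep.sum() == 0:
        warnings.warn("filter_expressed removed every gene", stacklevel=2)
    out = CountMatrix(
        cm.counts.loc[keep], cm.lengths.loc[keep], cm.library_sizes, cm.groups
    )
    return out, removed


def rpkm(count, gene_length_bp, library_size):
    """Reads per kilobase of exon per million mapped reads.

    ``1e9 * count / (library_size * gene_length_bp)``; accepts scalars or
    aligned arrays.
    """
    gene_length_bp = np.asarray(gene_length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(gene_length_bp <= 0):
        raise ValueError("gene length must be > 0")
    if np.any(library_size <= 0):
        raise ValueError("library size must be > 0")
    return 1e9 * np.asarray(count, dtype=float) / (library_size * gene_length_bp)


def fisher_de(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Two-sided Fisher's exact p for one gene between two pooled libraries.

    The 2x2 table is ``[[count_a, count_b], [lib_a - count_a, lib_b - count_b]]``.
    Two-sidedness follows the point-probability rule: the p-value sums the
    probabilities of all tables (same margins) whose point probability does
    not exceed that of the observed table.
    """
    return float(fisher_de_many([count_a], [count_b], lib_a, lib_b)[0])


def fisher_de_many(
    counts_a: Sequence[int] | np.ndarray,
    counts_b: Sequence[int] | np.ndarray,
    lib_a: int,
    lib_b: int,
) -> np.ndarray:
    """Vectorised :func:`fisher_de` over genes sharing the two library sizes."""
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    lib_a = int(lib_a)
    lib_b = int(lib_b)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be nonnegative")
    if (a > lib_a).any() or (b > lib_b).any():
        raise ValueError("library size must be >= its pooled count")
    n_total = lib_a + lib_b
    out = np.empty(a.shape, dtype=float)
    for i in range(a.size):
        n = int(a[i] + b[i])  # gene margin; conditioning statistic
        lo = max(0, n - lib_b)
        hi = min(n, lib_a)
        support = np.arange(lo, hi + 1)
        with np.errstate(divide="ignore"):
            logpmf = hypergeom.logpmf(support, n_total, lib_a, n)
        obs = logpmf[int(a[i]) - lo]
        out[i] = float(
            np.exp(logpmf[logpmf <= obs + np.log1p(_PG_RELTOL)]).sum()
        )
    return np.clip(out, 0.0, 1.0)


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = DE_ALPHA,
    log2fc_min: float = LOG2FC_MIN,
) -> pd.DataFrame:
    """Per-gene differential expression of ``group_b`` relative to ``group_a``.

    Replicates are pooled (summed) per group; each gene is tested by
    :func:`fisher_de` against the pooled library sizes, q-values come from
    :func:`bh_fdr` across genes, and log2FC is the log2 ratio of pooled
    RPKM (B over A) with a pseudocount of 0.5 on pooled counts so silenced
    genes keep a finite fold change.  Call is ``up`` when q <= alpha and
    log2FC > log2fc_min, ``down`` when q <= alpha and log2FC < -log2fc_min,
    else ``ns``.

    Returns a DataFrame indexed by gene with columns
    ``contrast, log2fc, p, q, call``.
    """
    pooled_a = cm.pooled_counts(group_a)
    pooled_b = cm.pooled_counts(group_b)
    lib_a = cm.pooled_library_size(group_a)
    lib_b = cm.pooled_library_size(group_b)
    p = fisher_de_many(pooled_a.values, pooled_b.values, int(lib_a), int(lib_b))
    q = bh_fdr(p)
    expr_a = rpkm(pooled_a.values + PSEUDOCOUNT, cm.lengths.values, lib_a)
    expr_b = rpkm(pooled_b.values + PSEUDOCOUNT, cm.lengths.values, lib_b)
    log2fc = np.log2(expr_b / expr_a)
    call = np.where(
        (q <= alpha) & (log2fc > log2fc_min),
        "up",
        np.where((q <= alpha) & (log2fc < -log2fc_min), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "contrast": f"{group_b}_vs_{group_a}",
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "call": call,
        },
        index=cm.genes,
    ).rename_axis("gene")
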