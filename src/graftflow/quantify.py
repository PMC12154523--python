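"""Expression quantification, differential calling, enrichment, qPCR.

Expression is quantified in FPKM (fragments per kilobase of transcript
per million mapped reads). Differential mobile transcripts are called at
the conventional thresholds |log2FC| >= 1 and Benjamini-Hochberg FDR
<= 0.05. The per-gene test is an exact binomial count test: conditional on
the gene's pooled count across both groups, the count observed in group A
is binomial with success probability equal to group A's share of the
total library size; two-sided p-values follow the minimum-likelihood rule.

Term enrichment of a gene set against user-supplied annotations uses the
one-sided hypergeometric (Fisher) tail; relative qPCR expression uses the
2^-ddCt method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix", "DifferentialCall", "compute_fpkm",
    "call_differential", "benjamini_hochberg", "hypergeometric_enrichment",
    "delta_delta_ct",
]


@dataclass
class ExpressionMatrix:
    """Counts plus the metadata needed to derive FPKM."""

    counts: pd.DataFrame        # genes x samples, non-negative integers
    gene_lengths: pd.Series     # nt per gene
    library_sizes: pd.Series    # mapped reads per sample
    fpkm: pd.DataFrame = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        lengths = self.gene_lengths.reindex(self.counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        libs = self.library_sizes.reindex(self.counts.columns)
        if libs.isna().any() or (libs <= 0).any():
            raise ValueError("every sample needs a positive library size")
        if self.fpkm is None:
            self.fpkm = (self.counts * 1e9).div(lengths, axis=0).div(libs, axis=1)


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * library_size[s]).

    When ``library_sizes`` is omitted, each sample's total counts are used.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    return ExpressionMatrix(counts=counts.astype(int),
                            gene_lengths=gene_lengths.astype(float),
                            library_sizes=library_sizes.astype(float))


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    log2_fc: float
    p_value: float
    fdr: float

    @property
    def is_significant(self) -> bool:
        return abs(self.log2_fc) >= 1.0 and self.fdr <= 0.05


def _exact_binomial_p(x: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood rule)."""
    if n == 0:
        return 1.0
    return stats.binomtest(x, n, p0).pvalue


def call_differential(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Call differential genes between two sample groups.

    log2FC = log2((mean FPKM_A + 1) / (mean FPKM_B + 1)); p-values from the
    exact binomial count test of the pooled group-A count against the
    library-size-expected share; BH-adjusted FDR across genes. The result
    frame has columns gene_id, log2_fc, p_value, fdr, is_significant and is
    sorted by p-value then gene id.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    missing = [s for s in list(group_a) + list(group_b)
               if s not in expr.counts.columns]
    if missing:
        raise KeyError(f"samples absent from the matrix: {missing}")
    lib_a = float(expr.library_sizes[list(group_a)].sum())
    lib_b = float(expr.library_sizes[list(group_b)].sum())
    p0 = lib_a / (lib_a + lib_b)
    mean_a = expr.fpkm[list(group_a)].mean(axis=1)
    mean_b = expr.fpkm[list(group_b)].mean(axis=1)
    log2_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    xa = expr.counts[list(group_a)].sum(axis=1)
    pooled = xa + expr.counts[list(group_b)].sum(axis=1)
    pvals = np.array([
        _exact_binomial_p(int(x), int(n), p0) for x, n in zip(xa, pooled)
    ])
    fdr = benjamini_hochberg(pvals)
    out = pd.DataFrame({
        "gene_id": expr.counts.index,
        "log2_fc": log2_fc.to_numpy(),
        "p_value": pvals,
        "fdr": fdr,
    })
    out["is_significant"] = (out["log2_fc"].abs() >= lfc_threshold) & (
        out["fdr"] <= fdr_threshold)
    return out.sort_values(["p_value", "gene_id"]).reset_index(drop=True)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values: q(i) = min_{j>=i} (m/j) p(j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def hypergeometric_enrichment(
    gene_set,
    annotation: dict[str, set[str]] | pd.DataFrame,
    universe,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``gene_set`` per term.

    ``annotation`` maps gene id -> iterable of term ids (or a two-column
    frame gene_id/term). For a term annotating K of the N universe genes
    with k hits among the n selected genes,
    p = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n). Terms with K = 0 are
    skipped; p-values are BH-adjusted across terms.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if isinstance(annotation, pd.DataFrame):
        ann: dict[str, set[str]] = {}
        gene_col, term_col = annotation.columns[:2]
        for g, t in zip(annotation[gene_col], annotation[term_col]):
            ann.setdefault(str(g), set()).add(str(t))
        annotation = ann
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene in universe:
            for t in terms:
                term_genes.setdefault(t, set()).add(gene)
    N, n = len(universe), len(gene_set)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "annotated": K, "hits": k,
                     "p_value": min(1.0, p)})
    result = pd.DataFrame(rows, columns=["term", "annotated", "hits", "p_value"])
    if len(result):
        result["fdr"] = benjamini_hochberg(result["p_value"].to_numpy())
    else:
        result["fdr"] = []
    return result


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the test sample minus the same
    difference in the calibrator sample; one extra cycle halves the
    estimate.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator,
           ct_ref_calibrator)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
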