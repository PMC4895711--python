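"""Normalization, expressed-gene cutoff, differential flags and TE.

Counts are normalized with the median-of-ratios size-factor estimator
(the estimator underlying DESeq): the reference per gene is the geometric
mean of its counts across samples, and each sample's size factor is the
median of count/reference over genes with all-positive counts.

The expressed-gene cutoff is the median normalized mRNA level of a
reference gene set (the secondary-metabolic genes, assumed minimal at
mid-exponential phase); a gene is expressed when it exceeds the cutoff in
at least one phase.

Differential flags use |fold-change| >= 2 AND p < 0.05 in >= 2 phase
contrasts.  The p-value comes from a two-sample negative-binomial test with
a normal approximation on the log scale: for single normalized values x1,
x2 per condition, Var(log K) ~ 1/mu + alpha under NB(mu, alpha), so

    z = (log(x1+c) - log(x2+c)) / sqrt(1/(x1+c) + 1/(x2+c) + 2*alpha)

with a half-count continuity constant c = 0.5.  The dispersion alpha is a
pooled method-of-moments estimate when replicate columns exist
(:func:`estimate_dispersion`); with merged one-column-per-phase data it is
not identifiable and a fixed default (0.05) is used.

TE = (RPF_norm + 1) / (mRNA_norm + 1); the pseudocount of 1 guards the
zero denominator and is applied at TE computation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel

__all__ = [
    "size_factors",
    "normalize",
    "rpkm",
    "expressed_cutoff",
    "exclude_terminal_genes",
    "estimate_dispersion",
    "differential_flags",
    "translation_efficiency",
    "te_log2fc",
    "DEFAULT_DISPERSION",
]

DEFAULT_DISPERSION = 0.05


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    Requires at least two samples and at least one gene with nonzero counts
    in every sample.
    """
    if matrix.shape[1] < 2:
        raise ValueError("size factors require >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene with positive counts in all samples")
    v = values[all_positive]
    log_ref = np.log(v).mean(axis=1)  # log geometric mean per gene
    sf = np.exp(np.median(np.log(v) - log_ref[:, None], axis=0))
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if not matrix.columns.equals(factors.index):
        raise ValueError("size factors do not match matrix samples")
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValueError("size factors must be finite and > 0")
    return matrix / factors


def rpkm(counts, gene_length, library_size) -> pd.Series | float:
    """Reads per kilobase of transcript per million mapped reads."""
    gene_length = np.asarray(gene_length, dtype=float)
    if np.any(gene_length <= 0):
        raise ValueError("gene length must be > 0")
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    out = np.asarray(counts, dtype=float) / (gene_length / 1e3) / (library_size / 1e6)
    if isinstance(counts, pd.Series):
        return pd.Series(out, index=counts.index)
    return out if out.ndim else float(out)


def expressed_cutoff(
    normalized_mrna: pd.DataFrame,
    reference_genes: Sequence[str],
    reference_phase: str = "M",
) -> tuple[float, pd.Series]:
    """Expressed-gene cutoff from a reference gene set.

    cutoff = median normalized expression of ``reference_genes`` at
    ``reference_phase``; a gene is expressed iff its normalized value is
    strictly greater than the cutoff in at least one phase.
    """
    reference_genes = [g for g in reference_genes]
    if not reference_genes:
        raise ValueError("reference gene set is empty")
    missing = set(reference_genes) - set(normalized_mrna.index)
    if missing:
        raise ValueError(f"reference genes absent from matrix: {sorted(missing)[:5]}")
    cutoff = float(normalized_mrna.loc[reference_genes, reference_phase].median())
    expressed = (normalized_mrna > cutoff).any(axis=1)
    expressed.name = "expressed"
    return cutoff, expressed


def exclude_terminal_genes(genes: Sequence[GeneModel], n_each: int = 20) -> list[str]:
    """Gene ids with the first and last ``n_each`` genes (by coordinate)
    removed — the chromosome-end duplications are excluded from all
    expression analyses."""
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    if len(ordered) <= 2 * n_each:
        return []
    return [g.gene_id for g in ordered[n_each : len(ordered) - n_each]]


def estimate_dispersion(matrix: pd.DataFrame, groups: Mapping[str, Sequence[str]]) -> float:
    """Pooled method-of-moments NB dispersion from replicate columns.

    For each gene and replicate group with mean m and variance v, the
    moment estimate is (v - m) / m^2; the pooled value is the median over
    all gene x group pairs with m > 0, clipped at 0.
    """
    ests = []
    for _, cols in groups.items():
        sub = matrix[list(cols)].to_numpy(dtype=float)
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        ests.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not ests:
        raise ValueError("dispersion estimation requires replicate groups")
    pooled = float(np.median(np.concatenate(ests)))
    return max(pooled, 0.0)


@dataclass
class DifferentialResult:
    """Per-contrast log2FC and p plus the combined per-gene flag."""

    log2fc: pd.DataFrame  # genes x contrasts
    pvalues: pd.DataFrame  # genes x contrasts
    flags: pd.Series  # bool per gene

    def summary(self) -> pd.DataFrame:
        out = pd.concat(
            {"log2fc": self.log2fc, "p": self.pvalues}, axis=1
        )
        out[("flag", "")] = self.flags
        return out


def differential_flags(
    normalized: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    dispersion: float = DEFAULT_DISPERSION,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_contrasts: int = 2,
) -> DifferentialResult:
    """Flag genes changing >= ``fc_threshold``-fold with p < ``alpha`` in at
    least ``min_contrasts`` contrasts (see module docstring for the test)."""
    if len(contrasts) < 2:
        raise ValueError("need >= 2 contrasts")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    c = 0.5
    fc_cols, p_cols = {}, {}
    for a, b in contrasts:
        x1 = normalized[a].to_numpy(dtype=float) + c
        x2 = normalized[b].to_numpy(dtype=float) + c
        log2fc = np.log2(x2) - np.log2(x1)
        z = (np.log(x2) - np.log(x1)) / np.sqrt(1.0 / x1 + 1.0 / x2 + 2.0 * dispersion)
        p = 2.0 * stats.norm.sf(np.abs(z))
        name = f"{a}:{b}"
        fc_cols[name] = log2fc
        p_cols[name] = p
    log2fc = pd.DataFrame(fc_cols, index=normalized.index)
    pvalues = pd.DataFrame(p_cols, index=normalized.index)
    hit = (log2fc.abs() >= np.log2(fc_threshold)) & (pvalues < alpha)
    flags = hit.sum(axis=1) >= min_contrasts
    flags.name = "differential"
    return DifferentialResult(log2fc=log2fc, pvalues=pvalues, flags=flags)


def translation_efficiency(
    rpf_norm: pd.DataFrame, mrna_norm: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """TE = (RPF + pseudocount) / (mRNA + pseudocount), per gene per phase."""
    if rpf_norm.shape != mrna_norm.shape or not rpf_norm.index.equals(mrna_norm.index) or not rpf_norm.columns.equals(mrna_norm.columns):
        raise ValueError("RPF and mRNA matrices must share genes and phases")
    return (rpf_norm + pseudocount) / (mrna_norm + pseudocount)


def te_log2fc(te: pd.DataFrame, contrast: tuple[str, str]) -> pd.Series:
    """log2 TE fold-change between two phases (difference of log2 TE)."""
    a, b = contrast
    out = np.log2(te[b]) - np.log2(te[a])
    out.name = f"{a}:{b}"
    return out
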