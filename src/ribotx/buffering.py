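"""Translational buffering, expression-pattern grouping and stoichiometry.

Translational buffering — ribosome occupancy changing less than mRNA
abundance — appears as a negative correlation between per-gene changes in
mRNA level and changes in translation efficiency across growth phases.
:func:`buffering_correlation` quantifies it with the Pearson r and the
least-squares slope of delta-log TE on delta-log mRNA.

Expression patterns over the four growth phases are grouped per modality
(mRNA and RPF) by hierarchical clustering of per-gene log2 profiles with
correlation distance (1 - Pearson r) and complete linkage, cut at k = 16
groups; the per-gene (mRNA group, RPF group) pair indexes a 16 x 16 = 256
cell combinatorial grid.  Monotone trends are additionally labelled I / D /
flat per modality, giving the II / ID / DI / DD anti-correlation groups.

Subunit stoichiometry: within an operon, length-normalized RPF levels are
expected proportional to annotated subunit copy numbers while mRNA levels
are uniform across the (co-transcribed) members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, leaves_list
from scipy.spatial.distance import pdist

from .core import GeneModel

__all__ = [
    "BufferingFit",
    "buffering_correlation",
    "heatmap_cluster",
    "pattern_groups",
    "PatternGroups",
    "trend_labels",
    "combined_trend",
    "stoichiometry_check",
]


@dataclass
class BufferingFit:
    r: float
    slope: float
    intercept: float
    pvalue: float
    n: int


def buffering_correlation(
    delta_log_mrna: pd.Series,
    delta_log_te: pd.Series,
    gene_subset: Optional[Sequence[str]] = None,
) -> BufferingFit:
    """Pearson r and least-squares slope of delta-log TE on delta-log mRNA."""
    x, y = delta_log_mrna.align(delta_log_te, join="inner")
    if gene_subset is not None:
        keep = x.index.intersection(pd.Index(gene_subset))
        x, y = x.loc[keep], y.loc[keep]
    mask = x.notna() & y.notna()
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("buffering correlation requires >= 3 genes")
    fit = stats.linregress(x.to_numpy(), y.to_numpy())
    return BufferingFit(
        r=float(fit.rvalue), slope=float(fit.slope), intercept=float(fit.intercept),
        pvalue=float(fit.pvalue), n=len(x),
    )


def heatmap_cluster(matrix: pd.DataFrame, metric: str = "manhattan", method: str = "complete"):
    """Agglomerative clustering of gene rows (manhattan distance, complete
    linkage by default).  Returns (leaf order as gene ids, scipy linkage
    matrix).  Deterministic given input order."""
    if matrix.shape[0] < 2:
        raise ValueError("clustering requires >= 2 genes")
    metric = "cityblock" if metric == "manhattan" else metric
    dist = pdist(matrix.to_numpy(dtype=float), metric=metric)
    Z = linkage(dist, method=method)
    order = [matrix.index[i] for i in leaves_list(Z)]
    return order, Z


@dataclass
class PatternGroups:
    """Per-gene expression-pattern group ids (1..k; 0 marks a flat profile)."""

    mrna_group: pd.Series
    rpf_group: pd.Series
    k: int

    @property
    def combinatorial(self) -> pd.Series:
        out = pd.Series(
            list(zip(self.mrna_group, self.rpf_group)),
            index=self.mrna_group.index,
            name="combinatorial_id",
        )
        return out


def _correlation_groups(matrix: pd.DataFrame, k: int) -> pd.Series:
    profiles = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    flat = profiles.std(axis=1) == 0  # constant profile: correlation undefined
    groups = pd.Series(0, index=matrix.index, dtype=int)
    idx = np.where(~flat)[0]
    if len(idx) < k:
        raise ValueError(f"need >= k={k} non-flat genes, got {len(idx)}")
    dist = pdist(profiles[idx], metric="correlation")
    Z = linkage(dist, method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust")
    groups.iloc[idx] = labels
    return groups


def pattern_groups(mrna_matrix: pd.DataFrame, rpf_matrix: pd.DataFrame, k: int = 16) -> PatternGroups:
    """Cluster per-gene phase profiles into k groups per modality
    (correlation distance, complete linkage, tree cut at k) and assign the
    combinatorial (mRNA, RPF) group id.  Genes with a constant profile get
    the reserved flat group 0."""
    if not mrna_matrix.index.equals(rpf_matrix.index):
        raise ValueError("mRNA and RPF matrices must share genes")
    mg = _correlation_groups(mrna_matrix, k)
    rg = _correlation_groups(rpf_matrix, k)
    mg.name, rg.name = "mrna_group", "rpf_group"
    return PatternGroups(mrna_group=mg, rpf_group=rg, k=k)


def trend_labels(profiles: pd.DataFrame, threshold: Optional[float] = None) -> pd.Series:
    """Label each gene's phase profile I (increasing), D (decreasing) or
    flat by the least-squares slope of log2(value+1) on phase index.

    Default threshold: the slope whose fitted end-to-end change across the
    profile equals 1 on the log2 scale, i.e. 1/(n_phases - 1).
    """
    n_phases = profiles.shape[1]
    if n_phases < 3:
        raise ValueError("trend labels require >= 3 phases")
    t = threshold if threshold is not None else 1.0 / (n_phases - 1)
    x = np.arange(n_phases, dtype=float)
    y = np.log2(profiles.to_numpy(dtype=float) + 1.0)
    xc = x - x.mean()
    slopes = (y - y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    labels = np.where(slopes > t, "I", np.where(slopes < -t, "D", "flat"))
    return pd.Series(labels, index=profiles.index, name="trend")


def combined_trend(mrna_labels: pd.Series, rpf_labels: pd.Series) -> pd.Series:
    """Combine per-modality trend labels into II/ID/DI/DD (flat elsewhere)."""
    out = mrna_labels.str.cat(rpf_labels)
    out = out.where(mrna_labels.isin(["I", "D"]) & rpf_labels.isin(["I", "D"]), other="flat")
    out.name = "trend_group"
    return out


def stoichiometry_check(rpf_matrix: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Observed vs expected RPF ratios within annotated operons.

    Per operon member and phase, the observed ratio is its length-normalized
    RPF divided by the first member's; per-phase ratios are combined as a
    geometric mean (each phase carries an independent, log-unbiased estimate
    of the same stoichiometric ratio, so averaging in log space weights the
    phases equally instead of letting the deepest phase dominate).  The
    expected ratio comes from the annotated subunit stoichiometry.  The
    first member (in genomic order) must have nonzero RPF in every phase.
    """
    rows = []
    operons: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.operon_id is not None:
            operons.setdefault(g.operon_id, []).append(g)
    for operon_id, members in operons.items():
        members = sorted(members, key=lambda g: g.start)
        if any(m.stoichiometry is None for m in members):
            raise ValueError(f"operon {operon_id}: missing stoichiometry annotation")
        dens = []
        for m in members:
            if m.gene_id not in rpf_matrix.index:
                raise ValueError(f"operon {operon_id}: gene {m.gene_id} absent from RPF matrix")
            dens.append(rpf_matrix.loc[m.gene_id].to_numpy(dtype=float) / (m.length / 1e3))
        if (dens[0] <= 0).any():
            raise ValueError(f"operon {operon_id}: first member has zero RPF")
        for m, d in zip(members, dens):
            expected = m.stoichiometry / members[0].stoichiometry
            with np.errstate(divide="ignore"):
                per_phase = np.log(d) - np.log(dens[0])
            observed = float(np.exp(per_phase.mean())) if np.isfinite(per_phase).all() else 0.0
            rows.append(
                {
                    "operon_id": operon_id,
                    "gene_id": m.gene_id,
                    "expected_ratio": expected,
                    "observed_ratio": observed,
                    "relative_error": abs(observed - expected) / expected,
                }
            )
    return pd.DataFrame(rows, columns=["operon_id", "gene_id", "expected_ratio", "observed_ratio", "relative_error"])
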