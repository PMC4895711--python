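"""TSS identification from differential 5'-end profiles (dRNA-seq).

Positions of 5' read ends in the TEX+ (exonuclease-treated) library are
potential TSSs.  The caller:

1. chains nonzero positions within ``cluster_gap`` (default 100 bp) into
   clusters, per strand;
2. drops clusters with fewer than ``min_reads`` total reads;
3. splits each cluster into sub-clusters by greedy left-to-right growth,
   extending while the sample standard deviation (n-1 divisor) of the
   member positions stays below ``sd_threshold`` (default 10);
4. drops sub-clusters with fewer than ``min_reads`` total reads;
5. designates the maximal peak of each sub-cluster as a candidate TSS
   (height ties broken towards the 5'-most position on the TSS strand);
6. within each original cluster, prunes groups of candidates whose
   positions have sd below the threshold down to the highest peak;
7. keeps only candidates supported by at least one TEX- (untreated) read
   within ``control_window`` bp — primary 5' ends persist in the untreated
   library, so an absent TEX- signal marks an artefact.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

from .core import CandidateTSS, FivePrimeProfile, PeakCluster

__all__ = [
    "position_sd",
    "partition_candidates",
    "subcluster_by_sd",
    "filter_min_reads",
    "select_subcluster_peaks",
    "prune_close_tss",
    "validate_against_control",
    "call_tss",
]


def position_sd(positions: Sequence[int]) -> float:
    """Sample standard deviation (divisor n-1) of genomic positions.

    A single position has sd 0 by convention; an empty input is an error.
    """
    n = len(positions)
    if n == 0:
        raise ValueError("position_sd requires at least one position")
    if n == 1:
        return 0.0
    mean = sum(positions) / n
    return math.sqrt(sum((p - mean) ** 2 for p in positions) / (n - 1))


def partition_candidates(profile: FivePrimeProfile, cluster_gap: int = 100) -> list[PeakCluster]:
    """Chain sorted nonzero positions into clusters while consecutive gaps
    stay <= ``cluster_gap``."""
    clusters: list[PeakCluster] = []
    cur_pos: list[int] = []
    cur_cnt: list[int] = []
    for pos in profile.positions():
        if cur_pos and pos - cur_pos[-1] > cluster_gap:
            clusters.append(PeakCluster(cur_pos, cur_cnt, profile.strand))
            cur_pos, cur_cnt = [], []
        cur_pos.append(pos)
        cur_cnt.append(profile.counts[pos])
    if cur_pos:
        clusters.append(PeakCluster(cur_pos, cur_cnt, profile.strand))
    return clusters


def subcluster_by_sd(cluster: PeakCluster, sd_threshold: float = 10.0) -> list[PeakCluster]:
    """Greedy left-to-right sub-clustering by positional sd.

    The current sub-cluster is extended with the next position while the sd
    of the extended member set stays strictly below ``sd_threshold``;
    otherwise a new sub-cluster starts.  Worked behaviour: (100, 114, 128)
    splits into {100, 114} (sd 9.9) and {128} since sd(100,114,128) = 14,
    whereas all 29 consecutive positions 100..128 stay together (sd 8.5).
    """
    if not cluster.positions:
        raise ValueError("cannot sub-cluster an empty cluster")
    subs: list[PeakCluster] = []
    cur: list[int] = [cluster.positions[0]]
    cur_cnt: list[int] = [cluster.counts[0]]
    for pos, cnt in zip(cluster.positions[1:], cluster.counts[1:]):
        if position_sd(cur + [pos]) < sd_threshold:
            cur.append(pos)
            cur_cnt.append(cnt)
        else:
            subs.append(PeakCluster(cur, cur_cnt, cluster.strand))
            cur, cur_cnt = [pos], [cnt]
    subs.append(PeakCluster(cur, cur_cnt, cluster.strand))
    return subs


def filter_min_reads(clusters: Iterable[PeakCluster], min_total: int = 3) -> list[PeakCluster]:
    """Drop clusters / sub-clusters whose total read count is below ``min_total``."""
    return [c for c in clusters if c.total >= min_total]


def select_subcluster_peaks(subclusters: Iterable[PeakCluster]) -> list[CandidateTSS]:
    """One candidate per sub-cluster at the maximal-count position.

    Height ties go to the 5'-most position on the sub-cluster's strand:
    the smallest coordinate on +, the largest on -.
    """
    out: list[CandidateTSS] = []
    for sub in subclusters:
        best = max(sub.counts)
        idxs = [i for i, c in enumerate(sub.counts) if c == best]
        i = idxs[0] if sub.strand == "+" else idxs[-1]
        out.append(CandidateTSS(position=sub.positions[i], strand=sub.strand, height=best))
    return out


def prune_close_tss(candidates: Sequence[CandidateTSS], sd_threshold: float = 10.0) -> list[CandidateTSS]:
    """Within one cluster, collapse groups of closely located candidates.

    Candidates (sorted by position) are grouped greedily with the same
    sd-growth rule as sub-clustering; within each group only the highest
    peak is retained (height tie -> 5'-most on the strand).
    """
    cands = sorted(candidates, key=lambda c: c.position)
    if not cands:
        return []
    groups: list[list[CandidateTSS]] = [[cands[0]]]
    for cand in cands[1:]:
        if position_sd([c.position for c in groups[-1]] + [cand.position]) < sd_threshold:
            groups[-1].append(cand)
        else:
            groups.append([cand])
    kept: list[CandidateTSS] = []
    for group in groups:
        best = max(c.height for c in group)
        tied = [c for c in group if c.height == best]
        kept.append(tied[0] if group[0].strand == "+" else tied[-1])
    return kept


def validate_against_control(
    candidates: Iterable[CandidateTSS], tex_minus: FivePrimeProfile, window: int = 5
) -> list[CandidateTSS]:
    """Keep candidates with any TEX- read within +/- ``window`` bp."""
    kept = []
    for cand in candidates:
        supported = any(
            tex_minus.counts.get(p, 0) > 0 for p in range(cand.position - window, cand.position + window + 1)
        )
        if supported:
            cand.validated = True
            kept.append(cand)
    return kept


def _by_strand(profiles) -> Mapping[str, FivePrimeProfile]:
    if isinstance(profiles, FivePrimeProfile):
        profiles = [profiles]
    if isinstance(profiles, Mapping):
        return profiles
    out = {}
    for p in profiles:
        if p.strand in out:
            raise ValueError(f"duplicate strand {p.strand} in profile list")
        out[p.strand] = p
    return out


def call_tss(
    tex_plus,
    tex_minus,
    cluster_gap: int = 100,
    sd_threshold: float = 10.0,
    min_reads: int = 3,
    control_window: int = 5,
) -> list[CandidateTSS]:
    """Full TSS caller: partition -> filter -> sub-cluster -> filter ->
    peak selection -> close-TSS pruning -> TEX- validation, per strand.

    ``tex_plus`` / ``tex_minus`` may each be a single profile, a list of
    per-strand profiles, or a strand -> profile mapping.  Output is sorted
    by position then strand.  The procedure is deterministic.
    """
    plus = _by_strand(tex_plus)
    minus = _by_strand(tex_minus)
    called: list[CandidateTSS] = []
    for strand, profile in plus.items():
        control = minus.get(strand, FivePrimeProfile(library="TEX_minus", strand=strand))
        clusters = filter_min_reads(partition_candidates(profile, cluster_gap), min_reads)
        for cluster in clusters:
            subs = filter_min_reads(subcluster_by_sd(cluster, sd_threshold), min_reads)
            cands = select_subcluster_peaks(subs)
            cands = prune_close_tss(cands, sd_threshold)
            called.extend(validate_against_control(cands, control, control_window))
    called.sort(key=lambda c: (c.position, c.strand))
    return called
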