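"""Classification of called TSSs against a gene annotation.

Each TSS receives exactly one class label (priority P > S > I > A > N):

* **P** (primary) / **S** (secondary): same-strand TSSs within the window
  from ``upstream`` bp (default 500) upstream to ``downstream`` bp (default
  150) downstream of a gene's annotated start codon.  Per gene, the highest
  peak is primary, the rest secondary.
* **I** (internal): inside an ORF on the same strand.
* **A** (antisense): inside an ORF span on the opposite strand.
* **N** (intergenic): none of the above — a novel transcript candidate.

5'-UTR lengths, leaderless/long-leader status, start-codon usage, the
nucleotide context around the TSS (+1), and sRNA candidates with their
ribosome-occupancy flag are derived here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import CandidateTSS, GeneModel, GenomeSequence, TSSRecord, revcomp

__all__ = [
    "classify_tss",
    "utr_length",
    "leader_status",
    "start_codon_usage",
    "tss_context",
    "ContextProfile",
    "srna_candidates",
]

#: 5'-UTRs shorter than this many nt mark a leaderless mRNA.
LEADERLESS_MAX_UTR = 9
#: 5'-UTRs longer than this many nt mark a long leader.
LONG_LEADER_MIN_UTR = 150


def _window_contains(gene: GeneModel, position: int, upstream: int, downstream: int) -> bool:
    """Strand-oriented window [start_codon - upstream, start_codon + downstream]."""
    sc = gene.start_codon_pos
    if gene.strand == "+":
        return sc - upstream <= position <= sc + downstream
    return sc - downstream <= position <= sc + upstream


def classify_tss(
    candidates: Sequence[CandidateTSS],
    genes: Sequence[GeneModel],
    upstream: int = 500,
    downstream: int = 150,
) -> list[TSSRecord]:
    """Assign one class label per candidate (see module docstring).

    A TSS whose window test succeeds for several genes is assigned to the
    gene with the nearest start codon.  Within a gene, the highest peak is
    primary (ties: closer to the start codon, then 5'-most on the strand).
    """
    assigned: dict[int, GeneModel] = {}  # candidate index -> gene (P/S pool)
    for i, cand in enumerate(candidates):
        eligible = [
            g
            for g in genes
            if g.strand == cand.strand and _window_contains(g, cand.position, upstream, downstream)
        ]
        if eligible:
            assigned[i] = min(
                eligible,
                key=lambda g: (abs(cand.position - g.start_codon_pos), g.gene_id),
            )

    per_gene: dict[str, list[int]] = {}
    for i, gene in assigned.items():
        per_gene.setdefault(gene.gene_id, []).append(i)

    labels: dict[int, str] = {}
    gene_of: dict[int, Optional[str]] = {}
    for gene_id, idxs in per_gene.items():
        gene = next(g for g in genes if g.gene_id == gene_id)

        def rank(i: int):
            cand = candidates[i]
            five_prime = cand.position if cand.strand == "+" else -cand.position
            return (-cand.height, abs(cand.position - gene.start_codon_pos), five_prime)

        primary = min(idxs, key=rank)
        for i in idxs:
            labels[i] = "P" if i == primary else "S"
            gene_of[i] = gene_id

    records: list[TSSRecord] = []
    for i, cand in enumerate(candidates):
        if i in labels:
            label, gid = labels[i], gene_of[i]
        else:
            gid = None
            same = [g for g in genes if g.strand == cand.strand and g.start <= cand.position <= g.end]
            anti = [g for g in genes if g.strand != cand.strand and g.start <= cand.position <= g.end]
            if same:
                label = "I"
            elif anti:
                label = "A"
            else:
                label = "N"
        rec = TSSRecord(
            position=cand.position,
            strand=cand.strand,
            height=cand.height,
            class_label=label,
            gene_id=gid,
        )
        if label in ("P", "S"):
            gene = next(g for g in genes if g.gene_id == gid)
            rec.utr_length = utr_length(rec, gene)
            rec.leader_status = leader_status(rec.utr_length) if rec.utr_length is not None else "undefined"
        records.append(rec)
    return records


def utr_length(record: TSSRecord, gene: GeneModel) -> Optional[int]:
    """Strand-oriented distance from the TSS to the start-codon first base.

    Returns None (undefined) when the TSS lies downstream of the start codon
    — a negative leader is meaningless and such TSSs are excluded from UTR
    statistics.
    """
    if record.class_label not in ("P", "S"):
        raise ValueError("UTR length is defined only for P/S TSSs")
    if gene.strand == "+":
        utr = gene.start - record.position
    else:
        utr = record.position - gene.end
    return utr if utr >= 0 else None


def leader_status(
    utr: int,
    leaderless_max: int = LEADERLESS_MAX_UTR - 1,
    long_leader_min: int = LONG_LEADER_MIN_UTR + 1,
) -> str:
    """Classify a defined 5'-UTR length: < 9 nt leaderless, > 150 nt long leader."""
    if utr is None:
        raise ValueError("leader status undefined for undefined UTR")
    if utr < 0:
        raise ValueError("UTR length must be non-negative")
    if utr <= leaderless_max:
        return "leaderless"
    if utr >= long_leader_min:
        return "long_leader"
    return "leadered"


def start_codon_usage(genes: Iterable[GeneModel], genome: GenomeSequence) -> pd.Series:
    """Fractions of ATG/GTG/TTG/CTG/other start codons (strand-aware)."""
    counts = {"ATG": 0, "GTG": 0, "TTG": 0, "CTG": 0, "other": 0}
    n = 0
    for gene in genes:
        if gene.strand == "+":
            lo, hi = gene.start, gene.start + 2
        else:
            lo, hi = gene.end - 2, gene.end
        if lo < 1 or hi > len(genome):
            import warnings

            warnings.warn(f"gene {gene.gene_id}: start codon outside genome; skipped", stacklevel=2)
            continue
        codon = genome.slice(lo, hi)
        if gene.strand == "-":
            codon = revcomp(codon)
        counts[codon if codon in counts else "other"] += 1
        n += 1
    if n == 0:
        raise ValueError("no usable genes for start-codon usage")
    return pd.Series({k: v / n for k, v in counts.items()})


@dataclass
class ContextProfile:
    """Nucleotide composition at offsets -2..+2 around the TSS (+1)."""

    fractions: pd.DataFrame  # index offsets -2..2, columns A/C/G/T
    purine_fraction: float  # A+G at +1
    n: int = 0


def tss_context(records: Sequence, genome: GenomeSequence) -> ContextProfile:
    """Per-offset base composition on the TSS strand, offsets -2..+2.

    TSSs closer than 2 bp to a genome edge are skipped.
    """
    offsets = range(-2, 3)
    tallies = {off: {"A": 0, "C": 0, "G": 0, "T": 0} for off in offsets}
    n = 0
    for rec in records:
        if rec.position - 2 < 1 or rec.position + 2 > len(genome):
            continue
        for off in offsets:
            pos = rec.position + off if rec.strand == "+" else rec.position - off
            base = genome.slice(pos, pos)
            if rec.strand == "-":
                base = revcomp(base)
            if base in tallies[off]:
                tallies[off][base] += 1
        n += 1
    if n == 0:
        raise ValueError("no TSS with full -2..+2 context")
    frac = pd.DataFrame(
        {base: [tallies[off][base] / n for off in offsets] for base in "ACGT"},
        index=list(offsets),
    )
    # renormalise rows in case of N bases
    frac = frac.div(frac.sum(axis=1), axis=0)
    purine = frac.loc[0, "A"] + frac.loc[0, "G"]  # offset 0 is the +1 site
    return ContextProfile(fractions=frac, purine_fraction=float(purine), n=n)


def srna_candidates(
    records: Sequence[TSSRecord],
    rpf_rpkm: Mapping[int, float],
    occupancy_threshold: float,
) -> list[tuple[TSSRecord, bool]]:
    """Novel-transcript (sRNA) candidates: all antisense (A) and intergenic
    (N) TSSs, flagged as ribosome-occupied ("coding") when their transcript's
    RPF RPKM reaches ``occupancy_threshold``.

    ``rpf_rpkm`` maps TSS position -> RPF RPKM of the candidate transcript;
    missing positions count as 0 (no occupancy).
    """
    out = []
    for rec in records:
        if rec.class_label in ("A", "N"):
            coding = rpf_rpkm.get(rec.position, 0.0) >= occupancy_threshold
            out.append((rec, coding))
    return out
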