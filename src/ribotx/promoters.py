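"""Promoter architecture: -10/-35 consensus scanning, spacers, G+C, TIR.

Windows are strand-oriented relative to the TSS (+1): the -10 search window
covers offsets -20..-1 (20 nt immediately upstream) and the -35 window
covers offsets -40..-25 (16 nt).  The scanned consensus hexamers are the
conserved -10 box TANNNT and the less conserved -35 box NTGACC (IUPAC
ambiguity codes).  The spacer is the number of nucleotides strictly between
the -35 hexamer 3' end and the -10 hexamer 5' end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .core import GeneModel, GenomeSequence, revcomp

__all__ = [
    "PromoterWindows",
    "MotifHit",
    "MINUS10_CONSENSUS",
    "MINUS35_CONSENSUS",
    "extract_windows",
    "scan_consensus",
    "best_hit",
    "flanked_motif",
    "spacer_length",
    "gc_content",
    "promoter_table",
    "tir_profile",
    "TIRProfile",
]

MINUS10_CONSENSUS = "TANNNT"
MINUS35_CONSENSUS = "NTGACC"

#: strand-oriented offset of the first base of each search window
MINUS10_WINDOW = (-20, -1)
MINUS35_WINDOW = (-40, -25)


@dataclass(frozen=True)
class PromoterWindows:
    tss_position: int
    strand: str
    minus10_window: str  # offsets -20..-1, 20 nt, TSS strand
    minus35_window: str  # offsets -40..-25, 16 nt, TSS strand

    def __post_init__(self) -> None:
        if len(self.minus10_window) != 20 or len(self.minus35_window) != 16:
            raise ValueError("window lengths must be exactly 20 and 16")


@dataclass(frozen=True)
class MotifHit:
    motif: str  # "minus10" or "minus35"
    offset: int  # strand-oriented offset of the hexamer's first base (negative)
    matched_hexamer: str


def strand_oriented_slice(genome: GenomeSequence, tss_position: int, strand: str, lo: int, hi: int) -> str:
    """Sequence at strand-oriented offsets lo..hi relative to the TSS (+1 = 0)."""
    if strand == "+":
        return genome.slice(tss_position + lo, tss_position + hi)
    return revcomp(genome.slice(tss_position - hi, tss_position - lo))


def extract_windows(record, genome: GenomeSequence) -> Optional[PromoterWindows]:
    """Extract the -10 and -35 search windows for one TSS.

    Returns None (with a warning) for TSSs closer than 40 bp to the genome
    edge on their strand.
    """
    pos, strand = record.position, record.strand
    edge_ok = pos - 40 >= 1 if strand == "+" else pos + 40 <= len(genome)
    if not edge_ok:
        warnings.warn(f"TSS at {pos}({strand}) within 40 bp of genome edge; skipped", stacklevel=2)
        return None
    return PromoterWindows(
        tss_position=pos,
        strand=strand,
        minus10_window=strand_oriented_slice(genome, pos, strand, *MINUS10_WINDOW),
        minus35_window=strand_oriented_slice(genome, pos, strand, *MINUS35_WINDOW),
    )


_IUPAC = {code: set(bases) for code, bases in ambiguous_dna_values.items()}


def iupac_match(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(b in _IUPAC[p] for b, p in zip(seq, pattern))


def scan_consensus(window: str, pattern: str, window_offset: int) -> list[MotifHit]:
    """All exact IUPAC matches of a hexamer ``pattern`` within ``window``.

    ``window_offset`` is the strand-oriented offset of the window's first
    base; hit offsets are reported on the same axis.
    """
    if len(pattern) != 6:
        raise ValueError("consensus pattern must be a hexamer")
    motif = "minus10" if pattern == MINUS10_CONSENSUS else "minus35"
    hits = []
    for i in range(len(window) - 5):
        hexamer = window[i : i + 6]
        if iupac_match(hexamer, pattern):
            hits.append(MotifHit(motif=motif, offset=window_offset + i, matched_hexamer=hexamer))
    return hits


def best_hit(hits: Sequence[MotifHit]) -> Optional[MotifHit]:
    """The primary hit: the match closest to the TSS (largest offset)."""
    return max(hits, key=lambda h: h.offset) if hits else None


def flanked_motif(record, genome: GenomeSequence, hit: MotifHit) -> Optional[str]:
    """Hexamer with its logo flanks: N8+hexamer+N7 (21 nt) for the -10 box,
    N4+hexamer+N6 (16 nt) for the -35 box.  None when a flank runs off the
    genome."""
    up, down = (8, 7) if hit.motif == "minus10" else (4, 6)
    lo, hi = hit.offset - up, hit.offset + 5 + down
    pos, strand = record.position, record.strand
    if strand == "+":
        if pos + lo < 1 or pos + hi > len(genome):
            return None
    else:
        if pos - hi < 1 or pos - lo > len(genome):
            return None
    return strand_oriented_slice(genome, pos, strand, lo, hi)


def spacer_length(minus10_hit: MotifHit, minus35_hit: MotifHit) -> int:
    """Nucleotides strictly between the -35 hexamer 3' end and the -10
    hexamer 5' end."""
    spacer = minus10_hit.offset - (minus35_hit.offset + 5) - 1
    if spacer < 0:
        raise ValueError("overlapping -10/-35 hexamers")
    return spacer


def gc_content(sequence: str) -> float:
    """(G+C) / (non-N length)."""
    if not sequence:
        raise ValueError("empty sequence")
    denom = sum(1 for b in sequence if b != "N")
    if denom == 0:
        raise ValueError("all-N sequence has undefined G+C")
    return sum(1 for b in sequence if b in "GC") / denom


def promoter_table(records: Iterable, genome: GenomeSequence) -> pd.DataFrame:
    """Per-TSS promoter summary: hexamers, offsets, spacer, promoter G+C.

    Promoter G+C is computed over the -40..-1 upstream region.  Spacer is
    defined only when both boxes are found and do not overlap.
    """
    rows = []
    for rec in records:
        pw = extract_windows(rec, genome)
        if pw is None:
            continue
        h10 = best_hit(scan_consensus(pw.minus10_window, MINUS10_CONSENSUS, MINUS10_WINDOW[0]))
        h35 = best_hit(scan_consensus(pw.minus35_window, MINUS35_CONSENSUS, MINUS35_WINDOW[0]))
        spacer = None
        if h10 and h35:
            try:
                spacer = spacer_length(h10, h35)
            except ValueError:
                spacer = None
        rows.append(
            {
                "position": rec.position,
                "strand": rec.strand,
                "minus10_hexamer": h10.matched_hexamer if h10 else None,
                "minus10_offset": h10.offset if h10 else None,
                "minus35_hexamer": h35.matched_hexamer if h35 else None,
                "minus35_offset": h35.offset if h35 else None,
                "spacer": spacer,
                "promoter_gc": gc_content(pw.minus35_window + strand_oriented_slice(genome, rec.position, rec.strand, -24, -1)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "strand",
            "minus10_hexamer",
            "minus10_offset",
            "minus35_hexamer",
            "minus35_offset",
            "spacer",
            "promoter_gc",
        ],
    )


@dataclass
class TIRProfile:
    """Translation-initiation-region composition for one gene group."""

    group: str
    gc: float  # G+C of the 20-nt TIR
    purine_by_offset: pd.Series  # offsets -20..-1
    sd_region_purine: float  # mean purine fraction over offsets -12..-8
    n: int


def tir_profile(
    groups: Mapping[str, Sequence[GeneModel]],
    genome: GenomeSequence,
    window: int = 20,
) -> dict[str, TIRProfile]:
    """Per-group TIR (20 nt upstream of the start codon) G+C and per-offset
    purine fractions; the -12..-8 mean tracks the Shine-Dalgarno region."""
    out: dict[str, TIRProfile] = {}
    for name, genes in groups.items():
        seqs = []
        for gene in genes:
            sc = gene.start_codon_pos
            if gene.strand == "+":
                lo, hi = sc - window, sc - 1
                if lo < 1:
                    continue
                seqs.append(genome.slice(lo, hi))
            else:
                lo, hi = sc + 1, sc + window
                if hi > len(genome):
                    continue
                seqs.append(revcomp(genome.slice(lo, hi)))
        if not seqs:
            raise ValueError(f"group {name!r}: no gene with a full TIR window")
        purine = pd.Series(
            [sum(1 for s in seqs if s[i] in "AG") / len(seqs) for i in range(window)],
            index=range(-window, 0),
        )
        out[name] = TIRProfile(
            group=name,
            gc=gc_content("".join(seqs)),
            purine_by_offset=purine,
            sd_region_purine=float(purine.loc[-12:-8].mean()),
            n=len(seqs),
        )
    return out
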