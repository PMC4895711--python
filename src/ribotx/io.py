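"""Readers and writers for the standard external formats.

The pipeline consumes FASTA (genome), GFF3 (annotation), 4-column bedGraph
(strand-specific 5'-end counts) and TSV count tables, and emits TSV/BED6.
All internal coordinates are 1-based inclusive; bedGraph and BED are 0-based
half-open and are converted at this boundary.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .core import FivePrimeProfile, FormatError, GeneModel, GenomeSequence, TSSRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts",
    "write_counts",
    "write_tss_table",
    "read_tss_table",
]


def read_fasta(path) -> GenomeSequence:
    """Read a single-chromosome genome FASTA.

    Only the first record is used; additional records are ignored with a
    warning (the target organisms carry one chromosome).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} FASTA records; using the first "
            f"({records[0].id}) — single-chromosome genomes only",
            stacklevel=2,
        )
    rec = records[0]
    return GenomeSequence(name=rec.id, sequence=str(rec.seq).upper())


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i : i + width] + "\n")


def _attr_first(feature, key: str):
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_gff(path) -> list[GeneModel]:
    """Read gene features from GFF3.

    Coordinates are kept 1-based inclusive as stored in GFF3.  Optional
    attributes ``category``, ``operon_id`` and ``stoichiometry`` populate the
    corresponding GeneModel fields, defaulting to "other"/None/None.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        gene_id = _attr_first(feat, "ID")
        if gene_id is None:
            raise FormatError(f"{path}: gene feature at {feat.start} lacks an ID attribute")
        if feat.end < feat.start:
            raise FormatError(f"{path}: gene {gene_id} has end < start")
        stoich = _attr_first(feat, "stoichiometry")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                category=_attr_first(feat, "category") or "other",
                operon_id=_attr_first(feat, "operon_id"),
                stoichiometry=int(stoich) if stoich is not None else None,
            )
        )
    return genes


def write_gff(genes: Sequence[GeneModel], path, seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: g.start):
            attrs = [f"ID={g.gene_id}", f"category={g.category}"]
            if g.operon_id is not None:
                attrs.append(f"operon_id={g.operon_id}")
            if g.stoichiometry is not None:
                attrs.append(f"stoichiometry={g.stoichiometry}")
            fh.write(
                "\t".join(
                    [seqid, "ribotx", "gene", str(g.start), str(g.end), ".", g.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )


def read_bedgraph(path, library: str, strand: str) -> FivePrimeProfile:
    """Read a 4-column bedGraph of 5'-end read counts into a profile.

    bedGraph intervals are 0-based half-open; each interval [s, e) with value
    v contributes v to every 1-based position s+1..e.  Overlapping intervals
    are summed.
    """
    profile = FivePrimeProfile(library=library, strand=strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                s, e, value = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate or value") from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            if e <= s:
                raise FormatError(f"{path}:{lineno}: empty/inverted interval [{s},{e})")
            for pos in range(s + 1, e + 1):
                profile.add(pos, value)
    return profile


def write_bedgraph(profile: FivePrimeProfile, path, chrom: str = "chr") -> None:
    """Write one 1-bp interval per stored position (exact round-trip)."""
    with open(path, "w") as fh:
        for pos in profile.positions():
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{profile.counts[pos]}\n")


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample TSV of raw counts (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene_id(s): {dups}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells in count matrix")
    try:
        out = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer cell in count matrix") from exc
    if not (out.to_numpy() == df.to_numpy()).all():
        raise FormatError(f"{path}: non-integer cell in count matrix")
    if (out.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative count")
    out.index.name = "gene_id"
    return out


def write_counts(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


_TSS_COLUMNS = ["position", "strand", "height", "class", "gene_id", "utr_length", "leader_status"]


def write_tss_table(records: Iterable[TSSRecord], path) -> None:
    """Write classified TSSs as TSV plus a BED6 companion (``<path>.bed``).

    Records are sorted by position then strand.  BED uses 0-based half-open
    single-base intervals, name = class label, score = peak height.
    """
    recs = sorted(records, key=lambda r: (r.position, r.strand))
    rows = [
        {
            "position": r.position,
            "strand": r.strand,
            "height": r.height,
            "class": r.class_label,
            "gene_id": r.gene_id if r.gene_id is not None else ".",
            "utr_length": r.utr_length if r.utr_length is not None else ".",
            "leader_status": r.leader_status,
        }
        for r in recs
    ]
    pd.DataFrame(rows, columns=_TSS_COLUMNS).to_csv(path, sep="\t", index=False)
    bed_path = Path(str(path)).with_suffix(Path(str(path)).suffix + ".bed")
    with open(bed_path, "w") as fh:
        for r in recs:
            fh.write(f"chr\t{r.position - 1}\t{r.position}\t{r.class_label}\t{r.height}\t{r.strand}\n")


def read_tss_table(path) -> list[TSSRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    records = []
    for _, row in df.iterrows():
        gene_id = None if row["gene_id"] in (".", "", None) or pd.isna(row["gene_id"]) else str(row["gene_id"])
        utr = row["utr_length"]
        utr = None if (pd.isna(utr) or utr == ".") else int(utr)
        records.append(
            TSSRecord(
                position=int(row["position"]),
                strand=str(row["strand"]),
                height=int(row["height"]),
                class_label=str(row["class"]),
                gene_id=gene_id,
                utr_length=utr,
                leader_status=str(row["leader_status"]),
            )
        )
    return records
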