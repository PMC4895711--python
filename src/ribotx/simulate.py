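"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a single
high-G+C bacterial chromosome; TEX+/TEX- strand-specific 5'-end profiles
with sharp peaks at planted TSSs (enriched in TEX+, retained at reduced
height in TEX-), RNA-processing-site peaks present only in TEX-, and
uniform background noise; and negative-binomial mRNA/RPF count matrices
over four growth phases (M, T, L, S) with planted per-gene fold-changes, a
planted translational-buffering slope, and operons whose RPF levels follow
annotated subunit stoichiometry while mRNA levels are uniform.

Sequence-level plants per TSS: a purine at +1, a TANNNT box at offsets
-12..-7 and an NTGACC box upstream of it at a spacer drawn from 15-20 nt;
leadered genes in the top TE quintile carry an AGGAGG Shine-Dalgarno at
-12..-7 of the start codon.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FivePrimeProfile, GeneModel, GenomeSequence, revcomp

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "ProfileSet",
    "simulate_genome_annotation",
    "simulate_5prime_profiles",
    "simulate_count_matrices",
    "simulate_all",
]

PHASES = ("M", "T", "L", "S")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 1
    genome_length: int = 100_000
    n_genes: int = 60
    n_tss: int = 50
    gc_content: float = 0.72
    leaderless_fraction: float = 0.21
    tss_height_mean: float = 50.0  # TEX+ peak height, NB mean (floored at 3)
    tex_minus_retention: float = 0.4  # fraction of TEX+ height kept in TEX-
    tex_minus_jitter: int = 2  # max |shift| of the TEX- peak from the TSS (bp)
    processing_site_rate: float = 0.5  # TEX- -only peaks per kb per strand
    background_rate: float = 2.0  # background reads per kb per strand per library
    nb_dispersion: float = 0.01  # NB dispersion of counts and peak heights
    buffering_slope: float = -0.5  # planted slope of dlogTE on dlogmRNA, in [-1, 0]
    phase_foldchange_sd: float = 1.5  # sd of per-gene log2FC vs phase M

    # TSS sequence context
    tss_purine_fraction: float = 0.88  # purine probability at +1
    utr_median: float = 44.0  # median leadered 5'-UTR length (nt)
    utr_log_sd: float = 0.9  # sigma of the lognormal UTR length model
    spacer_min: int = 15  # planted -35/-10 spacer range, inclusive
    spacer_max: int = 20
    start_codon_probs: dict = field(default_factory=lambda: {"ATG": 0.60, "GTG": 0.35, "TTG": 0.05})
    n_antisense_tss: int = 0  # extra TSSs inside ORFs, opposite strand
    n_intergenic_tss: int = 0  # extra TSSs in gene-free regions

    # expression model
    baseline_log2_mean: float = 9.0  # per-gene baseline log2 mean count
    baseline_log2_sd: float = 1.5
    te_offset_sd: float = 1.0  # per-gene log2 TE baseline spread
    rpf_noise_sd: float = 0.2  # extra per-gene-phase log2 noise on RPF changes
    secondary_fraction: float = 0.15  # genes tagged secondary_metabolic
    secondary_baseline_shift: float = -3.0  # low at mid-exponential phase
    secondary_trend: float = 1.0  # extra log2 induction per later phase
    operon_baseline_boost: float = 2.5  # operons are highly expressed
    operon_stoichiometries: dict = field(
        default_factory=lambda: {"op_rpl": [1, 4], "op_atp": [1, 10, 2, 1, 3, 1, 3, 1]}
    )

    def __post_init__(self) -> None:
        for name in ("gc_content", "leaderless_fraction", "tex_minus_retention", "secondary_fraction", "tss_purine_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.buffering_slope <= 0.0:
            raise ValueError("buffering_slope must be in [-1, 0]")
        if self.genome_length < 10 * self.n_genes * 100:
            raise ValueError("genome_length must be >= 1000 * n_genes for non-overlapping placement")
        if self.n_tss > self.n_genes:
            raise ValueError("n_tss cannot exceed n_genes (one primary TSS per gene)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)!r}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        import ast

        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                kwargs[key.strip()] = ast.literal_eval(value.strip())
        return cls(**kwargs)


@dataclass
class TruthTable:
    """Planted ground truth recoverable by the downstream stages."""

    tss_truth: pd.DataFrame  # position, strand, gene_id, is_leaderless, kind
    mrna_log2fc: pd.DataFrame  # genes x phases, phase M column is 0
    rpf_log2fc: pd.DataFrame
    stoichiometry_truth: dict  # operon_id -> list of subunit copy numbers
    te_offset: pd.Series  # per-gene log2 TE baseline
    baseline_log2: pd.Series  # per-gene log2 baseline mean

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.tss_truth.to_csv(d / "tss_truth.tsv", sep="\t", index=False)
        self.mrna_log2fc.to_csv(d / "mrna_log2fc.tsv", sep="\t", index_label="gene_id")
        self.rpf_log2fc.to_csv(d / "rpf_log2fc.tsv", sep="\t", index_label="gene_id")
        rows = [
            {"operon_id": op, "subunit_index": i, "stoichiometry": s}
            for op, stoichs in self.stoichiometry_truth.items()
            for i, s in enumerate(stoichs)
        ]
        pd.DataFrame(rows, columns=["operon_id", "subunit_index", "stoichiometry"]).to_csv(
            d / "stoichiometry_truth.tsv", sep="\t", index=False
        )


@dataclass
class ProfileSet:
    """The four 5'-end profiles: TEX+/TEX- on each strand."""

    tex_plus: dict  # strand -> FivePrimeProfile
    tex_minus: dict


_BASES = np.array(["A", "C", "G", "T"])


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _plant(arr: np.ndarray, tss_pos: int, strand: str, offset: int, seq: str) -> None:
    """Write ``seq`` at strand-oriented offsets starting at ``offset``
    relative to ``tss_pos`` (offset 0 = the +1 base)."""
    if strand == "+":
        start = tss_pos - 1 + offset
        arr[start : start + len(seq)] = list(seq)
    else:
        end = tss_pos - 1 - offset
        arr[end - len(seq) + 1 : end + 1] = list(revcomp(seq))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_base_probs(gc)))


def simulate_genome_annotation(config: SimulationConfig):
    """Random genome, non-overlapping annotation and the full truth table.

    Genes occupy one slot each along the chromosome with 250-bp margins;
    operon members are consecutive, co-stranded and share transcription
    parameters.  Raises when the slots are too small to hold a gene.
    """
    rng = np.random.default_rng([config.seed, 0])
    L, n = config.genome_length, config.n_genes
    slot = L // n
    margin = 250
    if slot < 2 * margin + 450:
        raise ValueError("genes cannot be placed without overlap: increase genome_length or reduce n_genes")

    arr = rng.choice(_BASES, size=L, p=_base_probs(config.gc_content))

    # --- operon layout: consecutive gene indices on the + strand
    operon_of: dict[int, tuple[str, int]] = {}
    next_idx = 2
    for op_id, stoichs in config.operon_stoichiometries.items():
        if next_idx + len(stoichs) > n:
            raise ValueError(f"not enough genes to host operon {op_id}")
        for j, s in enumerate(stoichs):
            operon_of[next_idx + j] = (op_id, s)
        next_idx += len(stoichs) + 1

    n_secondary = int(round(config.secondary_fraction * n))
    non_operon = [i for i in range(n) if i not in operon_of]
    secondary_idx = set(rng.choice(non_operon, size=min(n_secondary, len(non_operon)), replace=False).tolist())

    genes: list[GeneModel] = []
    for i in range(n):
        lo = i * slot + margin
        max_len = min(1500, slot - 2 * margin)
        length = int(rng.integers(450, max_len + 1))
        start = int(lo + rng.integers(0, slot - 2 * margin - length + 1))
        strand = "+" if i in operon_of else str(rng.choice(["+", "-"]))
        category = "secondary_metabolic" if i in secondary_idx else "other"
        op = operon_of.get(i)
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                start=start + 1,  # 1-based
                end=start + length,
                strand=strand,
                category=category,
                operon_id=op[0] if op else None,
                stoichiometry=op[1] if op else None,
            )
        )

    # --- plant one primary TSS for each of the first n_tss genes
    tss_rows = []
    by_strand: dict[str, list[int]] = {"+": [], "-": []}

    def _separated(pos: int, strand: str, min_dist: int = 25) -> bool:
        return all(abs(pos - p) >= min_dist for p in by_strand[strand])

    for i in range(config.n_tss):
        gene = genes[i]
        for _attempt in range(200):
            leaderless = bool(rng.random() < config.leaderless_fraction)
            if leaderless:
                utr = int(rng.integers(0, 9))
            else:
                utr = int(round(rng.lognormal(np.log(config.utr_median), config.utr_log_sd)))
                utr = min(max(utr, 9), 450)
            pos = gene.start - utr if gene.strand == "+" else gene.end + utr
            if 45 <= pos <= L - 45 and _separated(pos, gene.strand):
                break
        else:
            raise ValueError(f"could not place a separated TSS for gene {gene.gene_id}")
        by_strand[gene.strand].append(pos)
        tss_rows.append(
            {"position": pos, "strand": gene.strand, "gene_id": gene.gene_id, "is_leaderless": leaderless, "kind": "primary"}
        )
        _plant_tss_context(arr, rng, pos, gene.strand, config)

    # --- optional antisense / intergenic TSSs (novel-transcript truth)
    for kind, count in (("antisense", config.n_antisense_tss), ("intergenic", config.n_intergenic_tss)):
        planted = 0
        for _attempt in range(200 * max(count, 1)):
            if planted >= count:
                break
            if kind == "antisense":
                gene = genes[int(rng.integers(0, n))]
                strand = "-" if gene.strand == "+" else "+"
                lo_p = gene.start + 160 if strand == "+" else gene.start
                hi_p = gene.end if strand == "+" else gene.end - 160
                if hi_p <= lo_p:
                    continue
                pos = int(rng.integers(lo_p, hi_p + 1))
            else:
                i = int(rng.integers(0, n))
                pos = int(i * slot + rng.integers(30, margin - 60))
                strand = str(rng.choice(["+", "-"]))
            if not (45 <= pos <= L - 45 and _separated(pos, strand)):
                continue
            if _in_any_ps_window(pos, strand, genes):
                continue
            inside_same = _inside_same_strand_orf(pos, strand, genes)
            inside_anti = _inside_opposite_strand_orf(pos, strand, genes)
            if kind == "antisense" and (inside_same or not inside_anti):
                continue
            if kind == "intergenic" and (inside_same or inside_anti):
                continue
            by_strand[strand].append(pos)
            tss_rows.append({"position": pos, "strand": strand, "gene_id": None, "is_leaderless": False, "kind": kind})
            _plant_tss_context(arr, rng, pos, strand, config)
            planted += 1
        if planted < count:
            raise ValueError(f"could not place {count} {kind} TSSs")

    # --- expression truth
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    te_offset = rng.normal(0.0, config.te_offset_sd, size=n)
    fc = np.zeros((n, len(PHASES)))
    fc[:, 1:] = rng.normal(0.0, config.phase_foldchange_sd, size=(n, 3))
    rpf_noise = np.zeros((n, len(PHASES)))
    rpf_noise[:, 1:] = rng.normal(0.0, config.rpf_noise_sd, size=(n, 3))

    # operon members share transcription/translation parameters
    for op_id in config.operon_stoichiometries:
        members = [i for i, g in enumerate(genes) if g.operon_id == op_id]
        lead = members[0]
        baseline[members] = baseline[lead] + config.operon_baseline_boost
        te_offset[members] = te_offset[lead]
        fc[members] = fc[lead]
        rpf_noise[members] = rpf_noise[lead]

    sec = np.array([g.category == "secondary_metabolic" for g in genes])
    baseline[sec] += config.secondary_baseline_shift
    fc[sec, 1:] += config.secondary_trend * np.arange(1, 4)

    rpf_fc = fc * (1.0 + config.buffering_slope) + rpf_noise

    # --- plant start codons, then SD motifs for high-TE leadered genes
    codons = list(config.start_codon_probs)
    codon_p = np.array([config.start_codon_probs[c] for c in codons], dtype=float)
    codon_p = codon_p / codon_p.sum()
    utr_of = {r["gene_id"]: (r["position"], r["is_leaderless"]) for r in tss_rows if r["gene_id"]}
    q80 = np.quantile(te_offset, 0.8)
    for i, gene in enumerate(genes):
        codon = str(rng.choice(codons, p=codon_p))
        sc = gene.start_codon_pos
        _plant(arr, sc, gene.strand, 0, codon)
        leaderless = utr_of.get(gene.gene_id, (None, False))[1]
        if te_offset[i] >= q80 and not leaderless:
            tss_pos = utr_of.get(gene.gene_id, (None, None))[0]
            utr = abs(sc - tss_pos) if tss_pos is not None else None
            if utr is None or utr >= 13:
                _plant(arr, sc, gene.strand, -12, "AGGAGG")

    genome = GenomeSequence(name="synthetic_chromosome", sequence="".join(arr))
    truth = TruthTable(
        tss_truth=pd.DataFrame(tss_rows, columns=["position", "strand", "gene_id", "is_leaderless", "kind"]),
        mrna_log2fc=pd.DataFrame(fc, index=gene_ids, columns=list(PHASES)),
        rpf_log2fc=pd.DataFrame(rpf_fc, index=gene_ids, columns=list(PHASES)),
        stoichiometry_truth=dict(config.operon_stoichiometries),
        te_offset=pd.Series(te_offset, index=gene_ids, name="te_offset"),
        baseline_log2=pd.Series(baseline, index=gene_ids, name="baseline_log2"),
    )
    return genome, genes, truth


def _plant_tss_context(arr, rng, pos: int, strand: str, config: SimulationConfig) -> None:
    """Plant the +1 base and the -35/-10 promoter boxes for one TSS."""
    if rng.random() < config.tss_purine_fraction:
        plus1 = "G" if rng.random() < 0.55 else "A"
    else:
        plus1 = "C" if rng.random() < 0.7 else "T"
    _plant(arr, pos, strand, 0, plus1)
    nnn = _random_seq(rng, 3, config.gc_content)
    _plant(arr, pos, strand, -12, f"TA{nnn}T")  # -10 box at -12..-7
    spacer = int(rng.integers(config.spacer_min, config.spacer_max + 1))
    n1 = _random_seq(rng, 1, config.gc_content)
    _plant(arr, pos, strand, -18 - spacer, f"{n1}TGACC")  # -35 box


def _in_any_ps_window(pos: int, strand: str, genes, upstream: int = 500, downstream: int = 150) -> bool:
    for g in genes:
        if g.strand != strand:
            continue
        sc = g.start_codon_pos
        if (g.strand == "+" and sc - upstream <= pos <= sc + downstream) or (
            g.strand == "-" and sc - downstream <= pos <= sc + upstream
        ):
            return True
    return False


def _inside_same_strand_orf(pos, strand, genes) -> bool:
    return any(g.strand == strand and g.start <= pos <= g.end for g in genes)


def _inside_opposite_strand_orf(pos, strand, genes) -> bool:
    return any(g.strand != strand and g.start <= pos <= g.end for g in genes)


def _nb_sample(rng: np.random.Generator, mean, dispersion: float):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_5prime_profiles(
    genome: GenomeSequence, genes: Sequence[GeneModel], truth: TruthTable, config: SimulationConfig
) -> ProfileSet:
    """TEX+/TEX- 5'-end profiles per strand (see module docstring).

    TEX+ peak heights are NB(tss_height_mean) floored at 3 reads so every
    planted TSS passes the caller's count filter; the TEX- counterpart keeps
    ``tex_minus_retention`` of the height within +/-2 bp.  Processing-site
    peaks appear only in TEX-; uniform Poisson background hits both
    libraries.
    """
    rng = np.random.default_rng([config.seed, 1])
    L = len(genome)
    tex_plus = {s: FivePrimeProfile(library="TEX_plus", strand=s) for s in "+-"}
    tex_minus = {s: FivePrimeProfile(library="TEX_minus", strand=s) for s in "+-"}

    for row in truth.tss_truth.itertuples(index=False):
        height = max(3, int(_nb_sample(rng, config.tss_height_mean, config.nb_dispersion)))
        tex_plus[row.strand].add(int(row.position), height)
        if config.tex_minus_retention > 0:
            kept = max(1, int(round(height * config.tex_minus_retention)))
            j = config.tex_minus_jitter
            jitter = int(rng.integers(-j, j + 1)) if j > 0 else 0
            pos = min(max(int(row.position) + jitter, 1), L)
            tex_minus[row.strand].add(pos, kept)

    for strand in "+-":
        n_ps = rng.poisson(config.processing_site_rate / 1000.0 * L)
        for pos in rng.integers(1, L + 1, size=n_ps):
            h = max(1, int(_nb_sample(rng, config.tss_height_mean * 0.5, config.nb_dispersion)))
            tex_minus[strand].add(int(pos), h)
        for lib in (tex_plus, tex_minus):
            n_bg = rng.poisson(config.background_rate / 1000.0 * L)
            for pos in rng.integers(1, L + 1, size=n_bg):
                lib[strand].add(int(pos), 1)

    return ProfileSet(tex_plus=tex_plus, tex_minus=tex_minus)


def simulate_count_matrices(
    genes: Sequence[GeneModel], truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB mRNA and RPF count matrices over the four growth phases.

    Per gene g and phase p the mRNA mean is 2^(baseline_g + fc_gp) scaled by
    gene length; the RPF mean additionally carries the gene's TE offset, the
    buffered fold-change and the subunit stoichiometry factor, so that
    within an operon RPF means are proportional to stoichiometry while mRNA
    means are uniform.
    """
    rng = np.random.default_rng([config.seed, 2])
    gene_ids = [g.gene_id for g in genes]
    lengths = np.array([g.length for g in genes], dtype=float)
    stoich = np.array([g.stoichiometry if g.stoichiometry is not None else 1 for g in genes], dtype=float)
    baseline = truth.baseline_log2.loc[gene_ids].to_numpy()
    te_offset = truth.te_offset.loc[gene_ids].to_numpy()
    fc = truth.mrna_log2fc.loc[gene_ids].to_numpy()
    rpf_fc = truth.rpf_log2fc.loc[gene_ids].to_numpy()

    lf = lengths[:, None] / 1e3
    mrna_mean = np.exp2(baseline[:, None] + fc) * lf
    rpf_mean = np.exp2(baseline[:, None] + te_offset[:, None] + rpf_fc) * lf * stoich[:, None]

    mrna = pd.DataFrame(_nb_sample(rng, mrna_mean, config.nb_dispersion), index=gene_ids, columns=list(PHASES))
    rpf = pd.DataFrame(_nb_sample(rng, rpf_mean, config.nb_dispersion), index=gene_ids, columns=list(PHASES))
    mrna.index.name = rpf.index.name = "gene_id"
    return mrna, rpf


def simulate_all(config: SimulationConfig):
    """Genome, annotation, truth, 5'-end profiles and count matrices."""
    genome, genes, truth = simulate_genome_annotation(config)
    profiles = simulate_5prime_profiles(genome, genes, truth, config)
    mrna, rpf = simulate_count_matrices(genes, truth, config)
    return genome, genes, truth, profiles, mrna, rpf
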