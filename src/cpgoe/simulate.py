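"""Synthetic sequences, gene sets and annotated toy genomes with controlled
CpG depletion.

Sequences are drawn from a first-order Markov chain over {A,C,G,T}. The
baseline chain has every row equal to the base composition (p_A = p_T =
(1-gc)/2, p_C = p_G = gc/2), so bases are i.i.d.; CpG depletion is imposed by
multiplying the C->G transition probability by a factor d in (0, 1.5] and
renormalizing the C row. This mimics the *end state* of germ-line CpG decay
(methyl-CpG -> TpG over evolutionary time) without simulating mutation
through time: d < 1 depletes CpG, d = 1 leaves the chain i.i.d.

Because of the row renormalization the realized CpG[o/e] is not d itself; the
exact long-run expectation follows from the stationary distribution pi of the
chain:

    E[CpG o/e] -> P(G|C) / pi_G        (as length -> infinity)

:func:`expected_cpg_oe` computes this closed form and
:func:`depletion_for_target_oe` inverts it, which is how the preset study
conditions (gene-body mean 0.70 at transcript GC 0.3625, genome mean 0.79 at
genome GC 0.334, and the bimodal 0.35/0.85 two-class set) are calibrated.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .sequence_io import GeneModel, SequenceRecord, write_fasta, write_gff_genes

logger = logging.getLogger(__name__)

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
_BASE_BYTES = np.frombuffer(BASES.encode(), dtype=np.uint8)

# Study-condition constants the presets are calibrated to: the organism's
# transcriptome GC (36.25%), genome GC (33.4%), the unimodal gene-body mean
# (0.70), the genome-fragment mean (0.79), and the canonical bimodal
# low/high component locations (0.35 / 0.85).
TRANSCRIPT_GC = 0.3625
GENOME_GC = 0.334
GENE_BODY_TARGET_OE = 0.70
GENOME_TARGET_OE = 0.79
BIMODAL_TARGETS_OE = (0.35, 0.85)


@dataclass(frozen=True)
class ClassSpec:
    """Generating parameters for one gene class.

    ``cpg_depletion`` multiplies the C->G transition (d < 1 => depleted);
    lengths are drawn from a normal truncated below at ``length_min``.
    """

    label: str
    proportion: float
    cpg_depletion: float
    gc_fraction: float
    length_mean: float = 709.0
    length_sd: float = 600.0
    length_min: int = 150

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("class label must be non-empty")
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError("proportion must be in (0, 1]")
        if not 0.0 < self.cpg_depletion <= 1.5:
            raise ValueError("cpg_depletion must be in (0, 1.5]")
        if not 0.05 < self.gc_fraction < 0.95:
            raise ValueError("gc_fraction must be in (0.05, 0.95)")
        if self.length_min < 2:
            raise ValueError("length_min must be >= 2")

    @classmethod
    def from_target_oe(
        cls,
        label: str,
        proportion: float,
        target_oe: float,
        gc_fraction: float,
        **kwargs,
    ) -> "ClassSpec":
        """Build a class whose long-run CpG[o/e] expectation equals ``target_oe``."""
        d = depletion_for_target_oe(target_oe, gc_fraction)
        return cls(label, proportion, d, gc_fraction, **kwargs)

    @property
    def expected_oe(self) -> float:
        return expected_cpg_oe(self.gc_fraction, self.cpg_depletion)


@dataclass(frozen=True)
class GenomeSimSpec:
    """Specification of a synthetic annotated genome or gene set."""

    classes: tuple[ClassSpec, ...]
    n_genes: int
    intergenic_gc: float = GENOME_GC
    intergenic_depletion: float = 1.0
    scaffold_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.scaffold_count < 1:
            raise ValueError("scaffold_count must be >= 1")
        if not self.classes:
            raise ValueError("at least one class is required")
        total = sum(c.proportion for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        object.__setattr__(self, "classes", tuple(self.classes))


def build_transition_matrix(
    gc_fraction: float, cpg_depletion: float
) -> tuple[np.ndarray, np.ndarray]:
    """The depleted first-order chain and its stationary distribution.

    Rows/columns are ordered A, C, G, T. Every row equals the base
    composition except the C row, whose G entry is scaled by ``cpg_depletion``
    and renormalized. Returns (P, pi) with rows of P summing to 1 within
    1e-12 and pi the stationary distribution of P.
    """
    if not 0.05 < gc_fraction < 0.95:
        raise ValueError("gc_fraction must be in (0.05, 0.95)")
    if not 0.0 < cpg_depletion <= 1.5:
        raise ValueError("cpg_depletion must be in (0, 1.5]")
    at = (1.0 - gc_fraction) / 2.0
    cg = gc_fraction / 2.0
    base = np.array([at, cg, cg, at])
    P = np.tile(base, (4, 1))
    c_row = base.copy()
    c_row[G] *= cpg_depletion
    z = c_row.sum()
    if z < 1e-9:
        raise ValueError("C row degenerates under this depletion")
    P[C] = c_row / z
    pi = stationary_distribution(P)
    return P, pi


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a stochastic matrix (left eigenvector)."""
    n = P.shape[0]
    a = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def expected_cpg_oe(gc_fraction: float, cpg_depletion: float) -> float:
    """Long-run CpG[o/e] of the depleted chain: P(G|C) / pi_G.

    The observed CpG frequency per position converges to pi_C * P(G|C) and the
    expected frequency to pi_C * pi_G, so the ratio is P(G|C)/pi_G.
    """
    P, pi = build_transition_matrix(gc_fraction, cpg_depletion)
    return float(P[C, G] / pi[G])


def depletion_for_target_oe(target_oe: float, gc_fraction: float) -> float:
    """Invert the d -> CpG[o/e] map at a given GC fraction (numeric root)."""
    lo, hi = 1e-6, 1.5
    f = lambda d: expected_cpg_oe(gc_fraction, d) - target_oe
    if not f(lo) < 0.0 < f(hi) and not (f(lo) <= 0.0 <= f(hi)):
        raise ValueError(
            f"target CpG[o/e] {target_oe} unreachable at gc={gc_fraction} "
            f"(range {expected_cpg_oe(gc_fraction, lo):.4f}.."
            f"{expected_cpg_oe(gc_fraction, hi):.4f})"
        )
    return float(brentq(f, lo, hi, xtol=1e-12))


def _markov_codes(rng: np.random.Generator, length: int, P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Sample a state path of the chain; first state from pi."""
    if length < 1:
        raise ValueError("length must be >= 1")
    u = rng.random(length)
    pi_cum = np.cumsum(pi)
    state = int(np.searchsorted(pi_cum, u[0], side="right"))
    state = min(state, 3)
    cums = [tuple(row) for row in np.cumsum(P, axis=1)]
    out = [state]
    append = out.append
    for ui in u[1:].tolist():
        c0, c1, c2, _ = cums[state]
        if ui < c0:
            state = 0
        elif ui < c1:
            state = 1
        elif ui < c2:
            state = 2
        else:
            state = 3
        append(state)
    return np.asarray(out, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def generate_sequence(
    length: int, spec: ClassSpec, seed: int, seq_id: str | None = None
) -> SequenceRecord:
    """One Markov sequence under a class spec; deterministic given seed."""
    if length < 2:
        raise ValueError("length must be >= 2")
    P, pi = build_transition_matrix(spec.gc_fraction, spec.cpg_depletion)
    rng = np.random.default_rng(seed)
    codes = _markov_codes(rng, length, P, pi)
    return SequenceRecord(seq_id or f"{spec.label}_L{length}_s{seed}", _codes_to_str(codes))


def _draw_gene_plan(
    spec: GenomeSimSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class index and truncated-normal length for each gene."""
    props = np.array([c.proportion for c in spec.classes])
    class_idx = rng.choice(len(spec.classes), size=spec.n_genes, p=props)
    lengths = np.empty(spec.n_genes, dtype=np.int64)
    for i, ci in enumerate(class_idx):
        c = spec.classes[ci]
        lengths[i] = max(c.length_min, int(round(rng.normal(c.length_mean, c.length_sd))))
    return class_idx, lengths


def _truth_frame(spec: GenomeSimSpec, ids, class_idx, lengths) -> pd.DataFrame:
    rows = []
    for gid, ci, length in zip(ids, class_idx, lengths):
        c = spec.classes[ci]
        rows.append(
            (
                gid,
                c.label,
                c.cpg_depletion,
                c.gc_fraction,
                int(length),
                c.expected_oe,
                spec.seed,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "class_label",
            "cpg_depletion",
            "gc_fraction",
            "length",
            "expected_cpg_oe",
            "seed",
        ],
    )


def generate_gene_set(
    spec: GenomeSimSpec,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate a transcript-like gene set plus its truth table.

    Gene lengths come from each class's truncated normal; class membership is
    multinomial in the spec proportions. Returns (records, truth table) with
    one truth row per gene (label and generating parameters). Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    class_idx, lengths = _draw_gene_plan(spec, rng)
    chains = [build_transition_matrix(c.gc_fraction, c.cpg_depletion) for c in spec.classes]
    width = max(5, len(str(spec.n_genes)))
    records = []
    ids = []
    for i in range(spec.n_genes):
        gid = f"g{i + 1:0{width}d}"
        P, pi = chains[class_idx[i]]
        codes = _markov_codes(rng, int(lengths[i]), P, pi)
        records.append(SequenceRecord(gid, _codes_to_str(codes)))
        ids.append(gid)
    return records, _truth_frame(spec, ids, class_idx, lengths)


@dataclass(frozen=True)
class AnnotatedGenome:
    """A simulated genome with gene annotations and ground truth."""

    genome: tuple[SequenceRecord, ...]
    genes: tuple[GeneModel, ...]
    gene_sequences: tuple[SequenceRecord, ...]  # sense exonic (spliced) sequences
    truth: pd.DataFrame
    spec: GenomeSimSpec

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Write genome FASTA, GFF3, spliced-transcript FASTA, truth TSV."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        seed_tag = f"seed={self.spec.seed}"
        paths = {
            "genome": out_prefix.with_suffix(".genome.fa"),
            "gff": out_prefix.with_suffix(".genes.gff3"),
            "transcripts": out_prefix.with_suffix(".transcripts.fa"),
            "truth": out_prefix.with_suffix(".truth.tsv"),
        }
        write_fasta(
            self.genome,
            paths["genome"],
            descriptions={r.id: seed_tag for r in self.genome},
        )
        write_gff_genes(self.genes, paths["gff"], header_comments=[seed_tag])
        write_fasta(
            self.gene_sequences,
            paths["transcripts"],
            descriptions={r.id: seed_tag for r in self.gene_sequences},
        )
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def generate_annotated_genome(spec: GenomeSimSpec) -> AnnotatedGenome:
    """Simulate a genome FASTA + GFF3 + truth table.

    Genes are placed round-robin on ``scaffold_count`` scaffolds, separated by
    intergenic Markov sequence (``intergenic_gc``/``intergenic_depletion``).
    Each gene gets 1-3 exons; introns are carved between exon chunks and
    generated with the intergenic parameters. Scaffolds grow by concatenation,
    so genes never overlap and always lie within bounds. Extracting spliced
    gene bodies from the output reproduces the generated exonic sequences
    exactly (minus-strand genes are laid down reverse-complemented).
    """
    rng = np.random.default_rng(spec.seed)
    class_idx, lengths = _draw_gene_plan(spec, rng)
    gene_chains = [
        build_transition_matrix(c.gc_fraction, c.cpg_depletion) for c in spec.classes
    ]
    ig_P, ig_pi = build_transition_matrix(
        spec.intergenic_gc, spec.intergenic_depletion
    )
    width = max(5, len(str(spec.n_genes)))
    parts: list[list[str]] = [[] for _ in range(spec.scaffold_count)]
    cursors = [0] * spec.scaffold_count
    scaffold_ids = [f"scf{j + 1}" for j in range(spec.scaffold_count)]
    genes: list[GeneModel] = []
    gene_seqs: list[SequenceRecord] = []
    ids: list[str] = []
    for i in range(spec.n_genes):
        gid = f"g{i + 1:0{width}d}"
        ids.append(gid)
        scf = i % spec.scaffold_count
        length = int(lengths[i])
        P, pi = gene_chains[class_idx[i]]
        sense = _codes_to_str(_markov_codes(rng, length, P, pi))
        gene_seqs.append(SequenceRecord(gid, sense))
        # split into 1-3 exon chunks (transcript order)
        max_exons = min(3, length // 2)
        n_exons = int(rng.integers(1, max_exons + 1))
        if n_exons > 1:
            cuts = np.sort(
                rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)
            )
            bounds = [0, *cuts.tolist(), length]
        else:
            bounds = [0, length]
        chunks = [sense[bounds[j] : bounds[j + 1]] for j in range(n_exons)]
        introns = [
            _codes_to_str(_markov_codes(rng, int(rng.integers(50, 301)), ig_P, ig_pi))
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            placed_chunks = [_revcomp(c) for c in reversed(chunks)]
        else:
            placed_chunks = chunks
        gap = _codes_to_str(_markov_codes(rng, int(rng.integers(200, 801)), ig_P, ig_pi))
        parts[scf].append(gap)
        pos = cursors[scf] + len(gap)
        exon_intervals = []
        for j, chunk in enumerate(placed_chunks):
            exon_intervals.append((pos, pos + len(chunk)))
            parts[scf].append(chunk)
            pos += len(chunk)
            if j < len(placed_chunks) - 1:
                intron = introns[j]
                parts[scf].append(intron)
                pos += len(intron)
        cursors[scf] = pos
        genes.append(GeneModel(gid, scaffold_ids[scf], strand, tuple(exon_intervals)))
    genome = []
    for j in range(spec.scaffold_count):
        tail = _codes_to_str(_markov_codes(rng, int(rng.integers(200, 801)), ig_P, ig_pi))
        parts[j].append(tail)
        genome.append(SequenceRecord(scaffold_ids[j], "".join(parts[j])))
    truth = _truth_frame(spec, ids, class_idx, lengths)
    return AnnotatedGenome(
        genome=tuple(genome),
        genes=tuple(genes),
        gene_sequences=tuple(gene_seqs),
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Preset study conditions
# ---------------------------------------------------------------------------

def collembolan_like_spec(n_genes: int = 1500, seed: int = 0, **kwargs) -> GenomeSimSpec:
    """Single-class transcriptome: unimodal CpG[o/e], long-run mean 0.70.

    Emulates a springtail-like genome with no historical germ-line
    methylation: one gene class at transcript GC 36.25% calibrated to a
    long-run CpG[o/e] of 0.70, gene lengths echoing a transcriptome with mean
    ~709 bp; intergenic background at genome GC 33.4% calibrated to 0.79.
    """
    cls = ClassSpec.from_target_oe(
        "no_methylation", 1.0, GENE_BODY_TARGET_OE, TRANSCRIPT_GC
    )
    return GenomeSimSpec(
        classes=(cls,),
        n_genes=n_genes,
        intergenic_gc=GENOME_GC,
        intergenic_depletion=depletion_for_target_oe(GENOME_TARGET_OE, GENOME_GC),
        scaffold_count=3,
        seed=seed,
        **kwargs,
    )


def honeybee_like_spec(n_genes: int = 2000, seed: int = 0, **kwargs) -> GenomeSimSpec:
    """Two-class transcriptome: bimodal CpG[o/e] (components near 0.35/0.85).

    Emulates a genome with an intact germ-line methylation system: a 50/50
    split between a historically methylated (CpG-depleted, low o/e) and a
    historically unmethylated (high o/e) gene class.
    """
    lo, hi = BIMODAL_TARGETS_OE
    methylated = ClassSpec.from_target_oe("methylated", 0.5, lo, TRANSCRIPT_GC)
    unmethylated = ClassSpec.from_target_oe("unmethylated", 0.5, hi, TRANSCRIPT_GC)
    return GenomeSimSpec(
        classes=(methylated, unmethylated),
        n_genes=n_genes,
        intergenic_gc=GENOME_GC,
        intergenic_depletion=depletion_for_target_oe(GENOME_TARGET_OE, GENOME_GC),
        scaffold_count=3,
        seed=seed,
        **kwargs,
    )


def generate_background_genome(
    total_bp: int = 3_000_000,
    scaffold_count: int = 3,
    gc_fraction: float = GENOME_GC,
    target_oe: float = GENOME_TARGET_OE,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Uniform-depletion genome scaffolds calibrated to a target CpG[o/e].

    Study condition for the 1-kb-fragment analysis: a genome-wide background
    at the organism's genome GC with long-run CpG[o/e] at ``target_oe``.
    """
    d = depletion_for_target_oe(target_oe, gc_fraction)
    P, pi = build_transition_matrix(gc_fraction, d)
    rng = np.random.default_rng(seed)
    per = total_bp // scaffold_count
    return [
        SequenceRecord(f"scf{j + 1}", _codes_to_str(_markov_codes(rng, per, P, pi)))
        for j in range(scaffold_count)
    ]
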