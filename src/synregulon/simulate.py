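"""Synthetic inputs for every pipeline stage.

Generators produce background promoters at a specified GC fraction,
promoter sets with planted spaced dyads and a truth table, operon-
structured genomes with GFF3 annotations, HMMER-style per-domain hit
fixtures, and the probe-variant series used to interrogate arm
contributions in binding assays.  Every generator is a pure function of
its parameters and seed: reruns are byte-identical.

The background model is order-0 (independent bases with
P(G) = P(C) = gc/2 and P(A) = P(T) = (1 - gc)/2); real promoters carry
dinucleotide structure and compositional heterogeneity this model does
not emulate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, Genome, Promoter, reverse_complement
from .dyads import find_arms
from .scan import IUPAC_SETS

_BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic promoter set.

    Defaults mirror the study conditions: 400-bp upstream windows and, for
    genus-level fixtures, the genomic GC fraction of the modelled organism
    (55.95% for *Cloacibacillus evryensis* DSM 19522).
    """

    n_promoters: int = 20
    length: int = 400
    gc: float = 0.5595
    planted: tuple[str, int, str] | None = None
    plant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if not 0.0 <= self.plant_fraction <= 1.0:
            raise ValueError("plant_fraction must be in [0, 1]")
        if self.planted is not None:
            left, spacer, right = self.planted
            if self.length < len(left) + spacer + len(right):
                raise ValueError("promoter length smaller than planted span")


def gen_background(spec: SyntheticSpec) -> list[Promoter]:
    """Background promoters with independent bases at the spec's GC."""
    rng = np.random.default_rng(spec.seed)
    probs = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )
    width = len(str(max(spec.n_promoters, 1)))
    promoters = []
    for i in range(spec.n_promoters):
        bases = rng.choice(list(_BASES), size=spec.length, p=probs)
        promoters.append(
            Promoter(
                locus_id=f"p{i:0{width}d}",
                sequence="".join(bases),
                contig_id="synthetic",
                interval=(i * spec.length, (i + 1) * spec.length),
                strand="+",
            )
        )
    return promoters


def _instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Draw one concrete word from an IUPAC pattern (uniform per position)."""
    out = []
    for code in pattern:
        choices = sorted(IUPAC_SETS[code])
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def plant_dyad(
    promoters: Sequence[Promoter],
    dyad: tuple[str, int, str],
    fraction: float,
    seed: int,
) -> tuple[list[Promoter], pd.DataFrame]:
    """Plant one dyad instance in a random subset of promoters.

    ``dyad`` is (left arm, spacer length, right arm); arms may carry IUPAC
    degeneracy, instantiated independently per promoter.  The spacer is
    drawn from the promoters' own pooled base composition.  In each
    selected promoter the instance is written at a random valid offset on
    a random strand (written reverse-complemented for ``-``); all other
    bases are untouched.  Returns the modified promoters and a truth table
    (promoter_id, planted, offset, strand, left, spacer_seq, right).
    """
    left_pat, spacer_len, right_pat = dyad
    span = len(left_pat) + spacer_len + len(right_pat)
    for p in promoters:
        if len(p.sequence) < span:
            raise ValueError(
                f"promoter {p.locus_id} shorter ({len(p.sequence)}) than dyad span {span}"
            )
    rng = np.random.default_rng(seed)
    n_plant = round(fraction * len(promoters))
    chosen = set(
        rng.choice(len(promoters), size=n_plant, replace=False).tolist()
    )
    pooled = "".join(p.sequence for p in promoters)
    base_counts = np.array([pooled.count(b) for b in _BASES], dtype=float)
    base_probs = (
        base_counts / base_counts.sum() if base_counts.sum() else np.full(4, 0.25)
    )

    out: list[Promoter] = []
    rows = []
    for i, p in enumerate(promoters):
        if i not in chosen:
            out.append(p)
            rows.append((p.locus_id, False, -1, ".", "", "", ""))
            continue
        left = _instantiate_iupac(left_pat, rng)
        right = _instantiate_iupac(right_pat, rng)
        spacer = "".join(
            rng.choice(list(_BASES), size=spacer_len, p=base_probs)
        )
        instance = left + spacer + right
        offset = int(rng.integers(0, len(p.sequence) - span + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        written = instance if strand == "+" else reverse_complement(instance)
        seq = p.sequence[:offset] + written + p.sequence[offset + span :]
        out.append(replace(p, sequence=seq))
        rows.append((p.locus_id, True, offset, strand, left, spacer, right))
    truth = pd.DataFrame(
        rows,
        columns=["promoter_id", "planted", "offset", "strand", "left", "spacer_seq", "right"],
    )
    return out, truth


@dataclass
class SyntheticGenome:
    """A generated genome with its annotation and planting truth."""

    genome: Genome
    truth: pd.DataFrame  # one row per operon leader


def gen_synthetic_genome(
    n_operons: int,
    genes_per_operon: int,
    spec: SyntheticSpec,
    gene_length: int = 300,
    intra_operon_gap: int = 20,
) -> SyntheticGenome:
    """Operon-structured single-contig genome with optional planted motifs.

    The contig alternates promoter blocks (``spec.length`` bases of
    background, which also separate operons by far more than the operon
    gap threshold) and gene blocks whose intra-operon gaps stay below the
    grouping threshold.  Motifs are planted only in the promoter blocks of
    a seeded random subset of operon leaders (``spec.plant_fraction``).
    All genes lie on the forward strand so each promoter block is exactly
    the upstream window of its operon's leader.
    """
    if intra_operon_gap > 50:
        raise ValueError("intra_operon_gap must be <= 50 to keep operons intact")
    promo_spec = replace(spec, n_promoters=n_operons)
    promoters = gen_background(promo_spec)
    if spec.planted is not None and spec.plant_fraction > 0:
        promoters, truth = plant_dyad(
            promoters, spec.planted, spec.plant_fraction, spec.seed + 1
        )
    else:
        truth = pd.DataFrame(
            [(p.locus_id, False, -1, ".", "", "", "") for p in promoters],
            columns=["promoter_id", "planted", "offset", "strand", "left", "spacer_seq", "right"],
        )

    chunks: list[str] = []
    genes: list[GeneAnnotation] = []
    pos = 0
    rng = np.random.default_rng(spec.seed + 2)
    leader_ids = []
    for oi, promoter in enumerate(promoters):
        chunks.append(promoter.sequence)
        pos += len(promoter.sequence)
        for gi in range(genes_per_operon):
            gene_id = f"op{oi:03d}_g{gi}"
            if gi == 0:
                leader_ids.append(gene_id)
            gene_seq = "".join(
                rng.choice(list(_BASES), size=gene_length)
            )
            chunks.append(gene_seq)
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    contig_id="chr",
                    start=pos,
                    end=pos + gene_length,
                    strand="+",
                )
            )
            pos += gene_length
            if gi < genes_per_operon - 1:
                gap_seq = "".join(rng.choice(list(_BASES), size=intra_operon_gap))
                chunks.append(gap_seq)
                pos += intra_operon_gap
    genome = Genome(contigs={"chr": "".join(chunks)}, genes=genes)
    truth = truth.copy()
    truth["leader"] = leader_ids
    return SyntheticGenome(genome=genome, truth=truth)


# ---------------------------------------------------------------------------
# Domain-hit fixtures
# ---------------------------------------------------------------------------

_DOMTBL_HEADER = (
    "#                                                               "
    "--- full sequence --- -------------- this domain -------------   "
    "hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           "
    "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
    "i-Evalue  score  bias  from    to  from    to  from    to  acc "
    "description of target\n"
)


def _domtbl_row(
    protein: str, accession: str, i_evalue: float, rng: np.random.Generator
) -> str:
    tlen = int(rng.integers(200, 400))
    start = int(rng.integers(1, 50))
    end = start + int(rng.integers(60, 120))
    score = float(rng.uniform(10, 80))
    return (
        f"{protein:<20s} -            {tlen:4d} {accession.split('.')[0]:<20s} "
        f"{accession:<11s}  120 {i_evalue:9.2g} {score:6.1f}   0.1   1   1 "
        f"{i_evalue / 3:9.2g} {i_evalue:9.2g} {score:6.1f}   0.1     1   118 "
        f"{start:5d} {end:5d} {start:5d} {end:5d} 0.95 synthetic fixture\n"
    )


def gen_domtblout_fixture(
    n_proteins: int,
    n_with_both: int,
    n_with_one: int,
    seed: int,
    path: str | Path | None = None,
    n_boundary: int = 0,
    domain_a: str = "PF06018.12",
    domain_b: str = "PF08222.11",
    evalue_threshold: float = 1e-3,
) -> tuple[str, list[str]]:
    """Synthetic per-domain hit table plus the true candidate list.

    ``n_with_both`` proteins get significant hits to both domains,
    ``n_with_one`` a significant hit to one domain only, ``n_boundary``
    hits to both domains at exactly the threshold (excluded under the
    strict inequality), and the remainder either insignificant hits or
    none.  Returns the table text (also written to ``path`` if given) and
    the sorted list of proteins that truly pass the screen.
    """
    if n_with_both + n_with_one + n_boundary > n_proteins:
        raise ValueError("protein class counts exceed n_proteins")
    rng = np.random.default_rng(seed)
    buf = io.StringIO()
    buf.write(_DOMTBL_HEADER)
    truth = []
    width = len(str(max(n_proteins, 1)))
    for i in range(n_proteins):
        pid = f"prot{i:0{width}d}"
        strong = lambda: float(10 ** rng.uniform(-12, -4))
        weak = lambda: float(10 ** rng.uniform(-2.5, -0.5))
        if i < n_with_both:
            buf.write(_domtbl_row(pid, domain_a, strong(), rng))
            buf.write(_domtbl_row(pid, domain_b, strong(), rng))
            truth.append(pid)
        elif i < n_with_both + n_with_one:
            which = domain_a if rng.integers(2) == 0 else domain_b
            buf.write(_domtbl_row(pid, which, strong(), rng))
            other = domain_b if which == domain_a else domain_a
            if rng.integers(2) == 0:
                buf.write(_domtbl_row(pid, other, weak(), rng))
        elif i < n_with_both + n_with_one + n_boundary:
            buf.write(_domtbl_row(pid, domain_a, evalue_threshold, rng))
            buf.write(_domtbl_row(pid, domain_b, evalue_threshold, rng))
        else:
            if rng.integers(2) == 0:
                buf.write(_domtbl_row(pid, domain_a, weak(), rng))
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text, sorted(truth)


# ---------------------------------------------------------------------------
# Probe-variant design
# ---------------------------------------------------------------------------

PROBE_VARIANT_LABELS = ("I", "II", "III", "IV", "V", "VI")


def make_probe_variants(
    seq: str,
    arm_words: Sequence[str],
    seed: int = 0,
) -> dict[str, str]:
    """Design the six-probe arm-substitution series for a binding assay.

    Requires at least three arm occurrences in ``seq``.  Variant I is the
    unchanged probe; II, III and IV substitute the first, middle and last
    AT-rich arm with CCCCCC; V substitutes all three with GGGGGG; VI
    substitutes all three with seeded random hexamers each containing at
    least one G or C (so no variant retains an AT-rich arm).
    """
    occurrences = find_arms(seq, arm_words)
    if len(occurrences) < 3:
        raise ValueError(
            "probe design needs >= 3 arm occurrences; found offsets "
            f"{[o.offset for o in occurrences]}"
        )
    k = len(occurrences[0].word)
    first = occurrences[0]
    middle = occurrences[len(occurrences) // 2]
    last = occurrences[-1]

    def substitute(base_seq: str, targets, repl) -> str:
        s = list(base_seq)
        for occ, word in zip(targets, repl):
            s[occ.offset : occ.offset + k] = word
        return "".join(s)

    rng = np.random.default_rng(seed)

    def random_gc_word() -> str:
        while True:
            w = "".join(np.asarray(list(_BASES))[rng.integers(0, 4, size=k)])
            if any(c in "GC" for c in w):
                return w

    c_run, g_run = "C" * k, "G" * k
    all_three = (first, middle, last)
    return {
        "I": seq,
        "II": substitute(seq, [first], [c_run]),
        "III": substitute(seq, [middle], [c_run]),
        "IV": substitute(seq, [last], [c_run]),
        "V": substitute(seq, all_three, [g_run] * 3),
        "VI": substitute(seq, all_three, [random_gc_word() for _ in range(3)]),
    }
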