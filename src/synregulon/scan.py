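"""Genome-wide motif scanning and promoter classification.

Three matchers are provided:

* IUPAC patterns with a mismatch budget (both strands);
* spaced two-arm patterns ``left + N_d + right`` with a shared mismatch
  budget across the arms and an unconstrained spacer;
* position weight matrix (log-odds) scanning with exact p-values from a
  dynamic programme over the discretised score distribution, in the style
  of FIMO.

Promoters are then classified by whether they carry the canonical CodY
box, the extended palindromic dyad, both, or neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import Operon, Promoter, reverse_complement

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_iupac(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


class PatternError(ValueError):
    """Raised for patterns containing non-IUPAC characters."""


def _check_iupac(pattern: str) -> None:
    bad = set(pattern) - set(IUPAC_SETS)
    if bad:
        raise PatternError(f"non-IUPAC characters in pattern: {sorted(bad)}")


@dataclass(frozen=True)
class SpacedPattern:
    """A spaced (or contiguous) IUPAC pattern.

    Contiguous patterns are encoded as ``spacer_lens=(0,)`` with an empty
    right part.  ``max_mismatch`` is the shared budget across both arms;
    spacer bases are never constrained.
    """

    pattern_id: str
    left: str
    spacer_lens: tuple[int, ...] = (0,)
    right: str = ""
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        _check_iupac(self.left)
        _check_iupac(self.right)
        if self.max_mismatch < 0:
            raise PatternError("max_mismatch must be >= 0")
        if any(d < 0 for d in self.spacer_lens):
            raise PatternError("spacer lengths must be >= 0")
        object.__setattr__(self, "spacer_lens", tuple(sorted(set(self.spacer_lens))))

    @classmethod
    def contiguous(
        cls, pattern_id: str, pattern: str, max_mismatch: int = 0
    ) -> "SpacedPattern":
        return cls(pattern_id=pattern_id, left=pattern, max_mismatch=max_mismatch)


@dataclass(frozen=True)
class MotifHit:
    """A located motif match on one sequence."""

    sequence_id: str
    offset: int
    strand: str
    pattern_id: str
    mismatches: int | None = None
    spacer_len: int | None = None
    score: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class PromoterClass:
    """Canonical-box / extended-palindrome content of one promoter."""

    locus_id: str
    has_canonical: bool
    has_extended: bool

    @property
    def category(self) -> str:
        if self.has_canonical and self.has_extended:
            return "both"
        if self.has_canonical:
            return "canonical-only"
        if self.has_extended:
            return "extended-only"
        return "none"


def _mismatch_counts(seq: str, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` against every window of ``seq``.

    A sequence character matches an IUPAC class when it is a member of the
    class set; N in the sequence matches only the N class.
    """
    L = len(pattern)
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for j, code in enumerate(pattern):
        allowed = IUPAC_SETS[code]
        if code == "N":
            # N constrains nothing, including sequence N characters
            continue
        col = np.frombuffer(seq[j : j + n].encode(), dtype=np.uint8)
        ok = np.zeros(n, dtype=bool)
        for ch in allowed:
            ok |= col == ord(ch)
        counts += ~ok
    return counts


def scan_iupac(
    seq: str,
    pattern: SpacedPattern,
    max_mismatch: int | None = None,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """Scan both strands with a contiguous IUPAC pattern.

    A window is a hit when the number of positions violating the pattern's
    IUPAC classes is at most the mismatch budget.  Hits are reported at
    their forward-strand offset, ascending, ``+`` before ``-`` at equal
    offsets.
    """
    if pattern.right or pattern.spacer_lens != (0,):
        raise PatternError("scan_iupac requires a contiguous pattern")
    budget = pattern.max_mismatch if max_mismatch is None else max_mismatch
    pat = pattern.left
    L = len(pat)
    hits = []
    fwd = _mismatch_counts(seq, pat)
    rc_pat = reverse_complement_iupac(pat)
    rev = _mismatch_counts(seq, rc_pat)
    for off in range(len(fwd)):
        if fwd[off] <= budget:
            hits.append(
                MotifHit(sequence_id, off, "+", pattern.pattern_id, int(fwd[off]))
            )
        if rev[off] <= budget:
            hits.append(
                MotifHit(sequence_id, off, "-", pattern.pattern_id, int(rev[off]))
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_spaced(
    seq: str, pattern: SpacedPattern, sequence_id: str = "seq"
) -> list[MotifHit]:
    """Scan both strands with a spaced two-arm pattern.

    For each spacer length ``d`` the composite pattern
    ``left + N_d + right`` is matched under the shared mismatch budget.
    A motif span exceeding the sequence yields no hits (not an error).
    """
    hits = []
    for d in pattern.spacer_lens:
        composite = pattern.left + "N" * d + pattern.right
        L = len(composite)
        if L > len(seq):
            continue
        fwd = _mismatch_counts(seq, composite)
        rev = _mismatch_counts(seq, reverse_complement_iupac(composite))
        for off in range(len(fwd)):
            if fwd[off] <= pattern.max_mismatch:
                hits.append(
                    MotifHit(
                        sequence_id, off, "+", pattern.pattern_id,
                        int(fwd[off]), spacer_len=d,
                    )
                )
            if rev[off] <= pattern.max_mismatch:
                hits.append(
                    MotifHit(
                        sequence_id, off, "-", pattern.pattern_id,
                        int(rev[off]), spacer_len=d,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand, h.spacer_len))
    return hits


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values
# ---------------------------------------------------------------------------

@dataclass
class PWMModel:
    """Log-odds position weight matrix with an exact p-value table.

    ``matrix`` is 4 x L of log2(site frequency / background frequency),
    rows in A, C, G, T order.  Scores are discretised to integers at
    ``score_scale`` for the dynamic-programming p-value computation; the
    same discretisation is used when scoring windows, so table lookups are
    exact for every achievable score.
    """

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    score_scale: int = 1000
    pattern_id: str = "pwm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("matrix must be 4 x L with L >= 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix must be finite")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    @classmethod
    def from_frequencies(
        cls,
        freqs: np.ndarray,
        background: Sequence[float] | None = None,
        pseudo: float = 1e-3,
        **kwargs,
    ) -> "PWMModel":
        """Build a log-odds PWM from a column-stochastic frequency matrix."""
        bg = np.asarray(background if background is not None else np.full(4, 0.25))
        freqs = np.asarray(freqs, dtype=float)
        freqs = (freqs + pseudo) / (freqs + pseudo).sum(axis=0, keepdims=True)
        return cls(matrix=np.log2(freqs / bg[:, None]), background=bg, **kwargs)

    def integer_matrix(self) -> np.ndarray:
        return np.rint(self.matrix * self.score_scale).astype(np.int64)


def pwm_pvalue_table(pwm: PWMModel) -> "PWMPValueTable":
    """Exact distribution of PWM scores under the background model.

    Convolves the per-column score distributions over the discretised
    integer scores; the returned table maps any achievable integer score
    to ``P[score >= s]`` for a random background word.
    """
    q = pwm.integer_matrix()
    mins = q.min(axis=0)
    base = int(mins.sum())
    width = int((q.max(axis=0) - mins).sum())
    dist = np.zeros(width + 1)
    dist[0] = 1.0
    filled = 0
    for j in range(pwm.length):
        col_new = np.zeros(width + 1)
        for b in range(4):
            shift = int(q[b, j] - mins[j])
            col_new[shift : shift + filled + 1] += (
                pwm.background[b] * dist[: filled + 1]
            )
        dist = col_new
        filled += int(q[:, j].max() - mins[j])
    tail = np.cumsum(dist[::-1])[::-1]
    return PWMPValueTable(base=base, probabilities=dist, tail=tail)


@dataclass
class PWMPValueTable:
    """P[score >= s] lookup over the discretised score support."""

    base: int
    probabilities: np.ndarray
    tail: np.ndarray

    def pvalue(self, int_score: int) -> float:
        idx = int_score - self.base
        if idx < 0:
            return 1.0
        if idx >= len(self.tail):
            return 0.0
        return float(self.tail[idx])


def _integer_scores(seq: str, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer PWM score of every window; invalid windows flagged False."""
    L = q.shape[1]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = codes[j : j + n]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, q[np.clip(col, 0, 3), j], 0)
    return scores, valid


def pwm_scan(
    seq: str,
    pwm: PWMModel,
    p_threshold: float = 1e-4,
    table: PWMPValueTable | None = None,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """Scan both strands with a PWM, reporting hits with p <= threshold.

    Windows containing non-ACGT characters are skipped.  Hit offsets are
    forward-strand coordinates of the leftmost matched base.
    """
    if table is None:
        table = pwm_pvalue_table(pwm)
    q = pwm.integer_matrix()
    L = pwm.length
    hits = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        scores, valid = _integer_scores(s, q)
        for off in range(len(scores)):
            if not valid[off]:
                continue
            p = table.pvalue(int(scores[off]))
            if p <= p_threshold:
                genomic_off = off if strand == "+" else len(seq) - L - off
                hits.append(
                    MotifHit(
                        sequence_id,
                        genomic_off,
                        strand,
                        pwm.pattern_id,
                        score=float(scores[off]) / pwm.score_scale,
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg q-values for a list of p-values.

    Offered as an optional annotation column for PWM-mode hit tables;
    promoter classification itself applies no multiple-testing correction
    (it needs only motif existence).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    return q.tolist()


# ---------------------------------------------------------------------------
# Promoter classification (canonical box vs extended palindrome)
# ---------------------------------------------------------------------------

@dataclass
class ClassificationSummary:
    """Counts per category plus the regulon-size percentage of genes."""

    counts: dict[str, int]
    n_promoters: int
    n_genes: int | None = None
    n_target_genes: int | None = None
    percent_target_genes: float | None = None

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_promoters": self.n_promoters,
            "n_genes": self.n_genes,
            "n_target_genes": self.n_target_genes,
            "percent_target_genes": self.percent_target_genes,
        }


def classify_promoters(
    promoters: Sequence[Promoter],
    canonical: SpacedPattern,
    extended: SpacedPattern | PWMModel,
    operons: Sequence[Operon] | None = None,
    n_genes: int | None = None,
    p_threshold: float = 1e-4,
    leaders_only: bool = False,
) -> tuple[list[PromoterClass], ClassificationSummary]:
    """Classify promoters by canonical-box / extended-palindrome content.

    The percentage of target genes uses all annotated genes as the
    denominator; a motif on an operon leader's promoter credits every gene
    of that operon as a target (``leaders_only=True`` restricts the credit
    to the leader itself).
    """
    if isinstance(extended, PWMModel):
        table = pwm_pvalue_table(extended)

        def has_extended(p: Promoter) -> bool:
            return bool(pwm_scan(p.sequence, extended, p_threshold, table))

    else:

        def has_extended(p: Promoter) -> bool:
            return bool(scan_spaced(p.sequence, extended))

    classes = []
    for p in promoters:
        classes.append(
            PromoterClass(
                locus_id=p.locus_id,
                has_canonical=bool(scan_iupac(p.sequence, canonical)),
                has_extended=has_extended(p),
            )
        )
    counts = {"canonical-only": 0, "extended-only": 0, "both": 0, "none": 0}
    for c in classes:
        counts[c.category] += 1

    n_target = None
    percent = None
    if operons is not None:
        positive = {c.locus_id for c in classes if c.category != "none"}
        if leaders_only:
            n_target = len(positive)
        else:
            n_target = sum(
                len(op.gene_ids) for op in operons if op.leader in positive
            )
        if n_genes:
            percent = 100.0 * n_target / n_genes
    return classes, ClassificationSummary(
        counts=counts,
        n_promoters=len(classes),
        n_genes=n_genes,
        n_target_genes=n_target,
        percent_target_genes=percent,
    )
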