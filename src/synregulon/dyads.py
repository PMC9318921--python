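"""Spaced palindromic dyad discovery in promoter sets.

The binding site modelled here is a dyad: a short AT-rich arm, an
unconstrained spacer of d bases, and a second arm that is the (near)
reverse complement of the first — written ``ARM-N_d-rc(ARM)``.  Discovery
proceeds in three stages:

1. exhaustive enumeration of candidate (arm word, spacer length) pairs
   with promoter-support counting on both strands;
2. a binomial significance score against an order-0 background null,
   Bonferroni-corrected over all tested hypotheses;
3. ZOOPS ("zero or one occurrence per sequence") expectation-maximisation
   refinement of the seeded dyad into position frequency matrices and a
   spacer-length distribution.

The canonical Firmicutes CodY box and the reported Synergistetes genus
consensi are provided as module constants for convenience; they double as
worked-example inputs in the documentation.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from .genome import Promoter, reverse_complement

#: Canonical 15-base Firmicutes CodY operator (IUPAC; W = A/T).
CANONICAL_CODY_BOX = "AATTTTCWGAAAATT"

#: Published 36-base consensus upstream of xerC in Synergistes/Cloacibacillus.
SYNERGISTES_CONSENSUS = "AATTTTCTTAAAATTTCSCTTGATATTTACAATTTT"

#: Published genus-level dyads: left arm (IUPAC), spacer length, right arm.
GENUS_DYADS: dict[str, tuple[str, int, str]] = {
    "Synergistes/Cloacibacillus": ("AAAATT", 15, "AATTTT"),
    "Thermanaerovibrio": ("AATATT", 21, "AAAATA"),
    "Pyramidobacter": ("ATTTTY", 14, "AAAAAT"),
    "Acetomicrobium": ("WWTTTT", 12, "ATAATT"),
}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _normalize_dna(seq: str) -> str:
    """Map any character outside A/C/G/T to N (degenerate codes included)."""
    return "".join(c if c in "ACGT" else "N" for c in seq)


@dataclass(frozen=True)
class ArmOccurrence:
    """One exact match of an arm word (or its reverse complement)."""

    promoter_id: str
    offset: int
    word: str
    sense: str  # "forward-arm" | "reverse-arm"


@dataclass(frozen=True)
class DyadPair:
    """Two arm occurrences forming a reverse-complement pair on one strand."""

    left: ArmOccurrence
    right: ArmOccurrence

    @property
    def spacer(self) -> int:
        return self.right.offset - (self.left.offset + len(self.left.word))

    @property
    def span(self) -> int:
        return self.right.offset + len(self.right.word) - self.left.offset


@dataclass(frozen=True)
class DyadConfig:
    """Parameters of dyad enumeration and refinement.

    arm_len
        arm width in bases; 6 matches the reported genus consensi.
    spacer_min, spacer_max
        inclusive spacer-length range searched.
    min_at_fraction
        minimum A+T fraction for a candidate arm word; 5/6 admits the
        reported near-AT arms (e.g. ATTTTC) while excluding GC-rich words.
    palindrome_mismatch_max
        maximum Hamming distance allowed between the observed right arm and
        the reverse complement of the left arm.  The reported genus dyads
        include pairs two mismatches away from a perfect palindrome
        (AATATT/AAAATA), hence the default of 2.
    min_motif_span
        minimum full motif length 2*arm_len + spacer; 15 reflects the
        minimum palindrome length used for the original discovery.
    """

    arm_len: int = 6
    spacer_min: int = 0
    spacer_max: int = 30
    min_at_fraction: float = 5 / 6
    palindrome_mismatch_max: int = 2
    pseudocount: float = 0.1
    em_tolerance: float = 1e-6
    em_max_iter: int = 200
    seed: int = 0
    min_motif_span: int = 15

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")
        if not 0 <= self.min_at_fraction <= 1:
            raise ValueError("min_at_fraction must be in [0, 1]")
        if self.arm_len < 1:
            raise ValueError("arm_len must be >= 1")

    def spacer_range(self) -> list[int]:
        lo = max(self.spacer_min, self.min_motif_span - 2 * self.arm_len)
        return list(range(lo, self.spacer_max + 1))


@dataclass
class DyadModel:
    """A discovered dyad: arms, spacer, support and significance.

    Before EM refinement the arms are consensus words; after refinement
    ``left_matrix``/``right_matrix`` hold 4 x arm_len column-stochastic
    frequency matrices (rows in A, C, G, T order) and ``spacer_weights``
    a probability distribution over spacer lengths.
    """

    arm_len: int
    left_arm: str
    right_arm: str
    spacer_len: int
    support: int
    n_promoters: int
    p_value: float = 1.0
    left_matrix: np.ndarray | None = None
    right_matrix: np.ndarray | None = None
    spacer_weights: dict[int, float] | None = None
    site_prob: float | None = None
    log_likelihood: float | None = None

    @property
    def span(self) -> int:
        return 2 * self.arm_len + self.spacer_len

    def to_dict(self) -> dict:
        d = {
            "arm_len": self.arm_len,
            "left_arm": self.left_arm,
            "right_arm": self.right_arm,
            "spacer_len": self.spacer_len,
            "support": self.support,
            "n_promoters": self.n_promoters,
            "p_value": self.p_value,
            "site_prob": self.site_prob,
            "log_likelihood": self.log_likelihood,
        }
        if self.left_matrix is not None:
            d["left_matrix"] = self.left_matrix.tolist()
            d["right_matrix"] = self.right_matrix.tolist()
        if self.spacer_weights is not None:
            d["spacer_weights"] = {str(k): v for k, v in self.spacer_weights.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DyadModel":
        return cls(
            arm_len=d["arm_len"],
            left_arm=d["left_arm"],
            right_arm=d["right_arm"],
            spacer_len=d["spacer_len"],
            support=d["support"],
            n_promoters=d["n_promoters"],
            p_value=d.get("p_value", 1.0),
            left_matrix=(
                np.asarray(d["left_matrix"]) if "left_matrix" in d else None
            ),
            right_matrix=(
                np.asarray(d["right_matrix"]) if "right_matrix" in d else None
            ),
            spacer_weights=(
                {int(k): v for k, v in d["spacer_weights"].items()}
                if "spacer_weights" in d
                else None
            ),
            site_prob=d.get("site_prob"),
            log_likelihood=d.get("log_likelihood"),
        )

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load_json(cls, path: str | Path) -> "DyadModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Arm detection and pairing
# ---------------------------------------------------------------------------

def find_arms(
    seq: str, arm_words: Iterable[str], promoter_id: str = "seq"
) -> list[ArmOccurrence]:
    """Report every exact occurrence of an arm word or its reverse complement.

    Overlapping occurrences are all reported, in ascending offset.  A
    window equal to a designated forward word is labelled ``forward-arm``;
    a window equal only to a word's reverse complement is ``reverse-arm``.
    """
    words = sorted(set(arm_words))
    if not words:
        return []
    lengths = {len(w) for w in words}
    if len(lengths) > 1:
        raise ValueError(f"arm words must share one length, got {sorted(lengths)}")
    k = lengths.pop()
    forward = set(words)
    reverse = {reverse_complement(w) for w in words} - forward
    out = []
    for off in range(len(seq) - k + 1):
        window = seq[off : off + k]
        if window in forward:
            out.append(ArmOccurrence(promoter_id, off, window, "forward-arm"))
        elif window in reverse:
            out.append(ArmOccurrence(promoter_id, off, window, "reverse-arm"))
    return out


def pair_arms(
    occurrences: Sequence[ArmOccurrence], max_mismatch: int = 0
) -> list[DyadPair]:
    """Pair arm occurrences into reverse-complement dyads.

    Two occurrences (i left of j, non-overlapping) form a pair when the
    right word is within ``max_mismatch`` Hamming distance of the reverse
    complement of the left word.  Pairs are returned in (left offset,
    right offset) order.
    """
    pairs = []
    occ = sorted(occurrences, key=lambda o: o.offset)
    for a, b in itertools.combinations(occ, 2):
        if b.offset < a.offset + len(a.word):
            continue
        if hamming(b.word, reverse_complement(a.word)) <= max_mismatch:
            pairs.append(DyadPair(left=a, right=b))
    return pairs


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def at_fraction(word: str) -> float:
    return sum(c in "AT" for c in word) / len(word)


def candidate_arm_words(config: DyadConfig) -> list[str]:
    """All arm-length words over ACGT passing the A/T-fraction filter."""
    return [
        "".join(w)
        for w in itertools.product(_BASES, repeat=config.arm_len)
        if at_fraction("".join(w)) >= config.min_at_fraction
    ]


def _mismatch_neighbourhood(word: str, max_mismatch: int) -> list[str]:
    """All words within ``max_mismatch`` Hamming distance of ``word``."""
    out = set()
    positions = range(len(word))
    for k in range(max_mismatch + 1):
        for pos_combo in itertools.combinations(positions, k):
            alternatives = [
                [b for b in _BASES if b != word[p]] for p in pos_combo
            ]
            for subst in itertools.product(*alternatives):
                w = list(word)
                for p, b in zip(pos_combo, subst):
                    w[p] = b
                out.add("".join(w))
    return sorted(out)


# ---------------------------------------------------------------------------
# Background null and significance
# ---------------------------------------------------------------------------

def promoter_base_frequencies(promoters: Sequence[Promoter]) -> dict[str, float]:
    """Pooled A/C/G/T frequencies over a promoter set (order-0 background)."""
    counts = {b: 0 for b in _BASES}
    for p in promoters:
        for b in p.sequence:
            if b in counts:
                counts[b] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("promoters contain no A/C/G/T bases")
    return {b: counts[b] / total for b in _BASES}


def _neighbourhood_prob(
    word: str, bg: dict[str, float], max_mismatch: int
) -> float:
    """P(a background window is within max_mismatch of ``word``).

    Dynamic programme over positions tracking the running mismatch count;
    at each position a match contributes the background probability of the
    word's base, a mismatch the summed probability of the other bases.
    """
    state = [0.0] * (max_mismatch + 1)
    state[0] = 1.0
    for ch in word:
        p_match = bg.get(ch, 0.0)
        p_miss = 1.0 - p_match
        nxt = [0.0] * (max_mismatch + 1)
        for m, prob in enumerate(state):
            if prob == 0.0:
                continue
            nxt[m] += prob * p_match
            if m + 1 <= max_mismatch:
                nxt[m + 1] += prob * p_miss
        state = nxt
    return sum(state)


def background_word_prob(
    promoters: Sequence[Promoter],
    word: str,
    spacer: int,
    mismatch_max: int = 0,
) -> float:
    """Per-promoter probability of a dyad occurrence under the background.

    Under an order-0 background estimated from pooled promoter base
    frequencies, a site at one position requires the left arm to match
    ``word`` exactly and the right arm to fall within ``mismatch_max``
    Hamming distance of ``reverse_complement(word)``; the spacer positions
    are unconstrained.  With ``p_site`` that per-position probability and
    ``S`` the number of valid start positions in a promoter of the median
    length, the per-promoter probability is ``1 - (1 - p_site)**(2 S)``
    (both strands), clamped to [0, 1).
    """
    if not promoters:
        raise ValueError("promoter set is empty")
    bg = promoter_base_frequencies(promoters)
    p_left = 1.0
    for ch in word:
        p_left *= bg.get(ch, 0.0)
    p_right = _neighbourhood_prob(reverse_complement(word), bg, mismatch_max)
    p_site = p_left * p_right
    span = 2 * len(word) + spacer
    lengths = sorted(len(p.sequence) for p in promoters)
    median_len = lengths[len(lengths) // 2]
    n_starts = max(0, median_len - span + 1)
    if n_starts == 0 or p_site <= 0.0:
        return 0.0
    p0 = 1.0 - (1.0 - p_site) ** (2 * n_starts)
    return min(max(p0, 0.0), 1.0 - 1e-15)


def score_dyad_significance(k: int, n: int, p0: float, m: int = 1) -> float:
    """Bonferroni-corrected binomial upper tail P[X >= k | n, p0] * m.

    ``k`` is the promoter support of a dyad, ``n`` the promoter count,
    ``p0`` the per-promoter null occurrence probability and ``m`` the
    number of (word, spacer) hypotheses tested.  The result is clamped
    to at most 1.
    """
    if not (0 <= k <= n):
        raise ValueError(f"support k={k} outside [0, n={n}]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0={p0} outside [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    tail = float(binom.sf(k - 1, n, p0))
    return min(1.0, tail * m)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def _index_words(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for off in range(len(seq) - k + 1):
        w = seq[off : off + k]
        if "N" in w:
            continue
        index.setdefault(w, []).append(off)
    return index


@dataclass
class DyadEnumeration:
    """Ranked dyad models plus the hypothesis count used for correction."""

    models: list[DyadModel]
    n_hypotheses: int
    n_promoters: int


def enumerate_dyads(
    promoters: Sequence[Promoter], config: DyadConfig | None = None
) -> DyadEnumeration:
    """Exhaustive (arm word, spacer) dyad search with binomial significance.

    For every candidate arm word ``w`` (A/T fraction filter) and every
    spacer ``d`` with ``2*arm_len + d >= min_motif_span``, count the
    promoters containing ``w + N_d + w'`` on either strand, where ``w'``
    is within ``palindrome_mismatch_max`` mismatches of
    ``reverse_complement(w)``.  Each supported hypothesis receives a
    Bonferroni-corrected binomial p-value; models are ranked by ascending
    p-value, ties broken by higher support then lexicographic (word,
    spacer).  Zero-support hypotheses are counted for the correction but
    not returned.
    """
    config = config or DyadConfig()
    if not promoters:
        raise ValueError("promoter set is empty")
    words = candidate_arm_words(config)
    spacers = config.spacer_range()
    n_hyp = len(words) * len(spacers)
    if n_hyp == 0:
        return DyadEnumeration(models=[], n_hypotheses=0, n_promoters=len(promoters))

    k = config.arm_len
    indexes = []
    for p in promoters:
        seq = _normalize_dna(p.sequence)
        fwd = _index_words(seq, k)
        rev = _index_words(reverse_complement(seq), k)
        indexes.append((fwd, rev))

    spacer_set = set(spacers)
    support: dict[tuple[str, int], set[int]] = {}
    for w in words:
        rc = reverse_complement(w)
        neighbours = _mismatch_neighbourhood(rc, config.palindrome_mismatch_max)
        for pi, strands in enumerate(indexes):
            for index in strands:
                lefts = index.get(w)
                if not lefts:
                    continue
                rights: list[int] = []
                for nb in neighbours:
                    rights.extend(index.get(nb, ()))
                if not rights:
                    continue
                for lo in lefts:
                    for ro in rights:
                        d = ro - lo - k
                        if d in spacer_set:
                            support.setdefault((w, d), set()).add(pi)

    n = len(promoters)
    models = []
    p_right_cache: dict[str, float] = {}
    bg = promoter_base_frequencies(promoters)
    lengths = sorted(len(p.sequence) for p in promoters)
    median_len = lengths[len(lengths) // 2]
    for (w, d), members in support.items():
        if w not in p_right_cache:
            p_left = 1.0
            for ch in w:
                p_left *= bg.get(ch, 0.0)
            p_right_cache[w] = p_left * _neighbourhood_prob(
                reverse_complement(w), bg, config.palindrome_mismatch_max
            )
        p_site = p_right_cache[w]
        n_starts = max(0, median_len - (2 * k + d) + 1)
        if n_starts == 0 or p_site <= 0.0:
            p0 = 0.0
        else:
            p0 = min(1.0 - 1e-15, 1.0 - (1.0 - p_site) ** (2 * n_starts))
        models.append(
            DyadModel(
                arm_len=k,
                left_arm=w,
                right_arm=reverse_complement(w),
                spacer_len=d,
                support=len(members),
                n_promoters=n,
                p_value=score_dyad_significance(len(members), n, p0, n_hyp),
            )
        )
    models.sort(key=lambda mdl: (mdl.p_value, -mdl.support, mdl.left_arm, mdl.spacer_len))
    return DyadEnumeration(models=models, n_hypotheses=n_hyp, n_promoters=n)


# ---------------------------------------------------------------------------
# ZOOPS expectation-maximisation refinement
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def _column_scores(codes: np.ndarray, log_ratio: np.ndarray, k: int) -> np.ndarray:
    """Sliding log-likelihood-ratio of a k-column matrix over a sequence.

    ``log_ratio`` is 4 x k of log(theta / background).  Windows containing
    non-ACGT characters score -inf.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, log_ratio[np.clip(col, 0, 3), j], 0.0)
    scores[~valid] = -np.inf
    return scores


def refine_em(
    promoters: Sequence[Promoter],
    seed_model: DyadModel,
    config: DyadConfig | None = None,
    trace: list[float] | None = None,
) -> DyadModel:
    """Refine a seeded dyad with ZOOPS expectation-maximisation.

    The latent variable of a promoter is "no site" (probability
    ``1 - gamma``) or a single site described by (offset, spacer length,
    strand), with offsets and strands uniform and spacer lengths weighted
    by a learned distribution over ``[spacer_min, spacer_max]``.  Arm
    columns follow position frequency matrices with a symmetric Dirichlet
    pseudocount; spacer and flanking bases follow the fixed order-0
    background.  The reported ``log_likelihood`` is the penalised
    (maximum a posteriori) objective, which is non-decreasing across
    iterations; the run is fully deterministic given the seed model.
    If ``trace`` is a list, the objective of every iteration is appended
    to it.
    """
    config = config or DyadConfig()
    if not promoters:
        raise ValueError("promoter set is empty")
    k = seed_model.arm_len
    bg_freqs = promoter_base_frequencies(promoters)
    bg = np.array([max(bg_freqs[b], 1e-9) for b in _BASES])
    bg /= bg.sum()
    log_bg = np.log(bg)

    spacers = [
        d
        for d in range(config.spacer_min, config.spacer_max + 1)
        if 2 * k + d >= config.min_motif_span
    ]
    if seed_model.spacer_len not in spacers:
        spacers = sorted(set(spacers) | {seed_model.spacer_len})
    n_d = len(spacers)

    def seeded_matrix(word: str) -> np.ndarray:
        mat = np.full((4, k), 0.5)
        for j, ch in enumerate(word):
            mat[_BASE_INDEX[ch], j] += 3.0
        return mat / mat.sum(axis=0, keepdims=True)

    theta_l = seeded_matrix(seed_model.left_arm)
    theta_r = seeded_matrix(seed_model.right_arm)
    lam = np.full(n_d, 0.5 / max(1, n_d - 1)) if n_d > 1 else np.array([1.0])
    if n_d > 1:
        lam[spacers.index(seed_model.spacer_len)] = 0.5
    gamma = 0.5
    pc = config.pseudocount

    seqs = []
    for p in promoters:
        seq = _normalize_dna(p.sequence)
        fwd = _encode(seq)
        rev = _encode(reverse_complement(seq))
        seqs.append((fwd, rev))

    def objective_terms(theta: np.ndarray) -> float:
        # Dirichlet(pc + 1) log-prior on each matrix column (MAP penalty)
        return float(pc * np.sum(np.log(theta)))

    prev_obj = -np.inf
    objective_history: list[float] = []
    for iteration in range(config.em_max_iter):
        log_l = np.log(theta_l) - log_bg[:, None]
        log_r = np.log(theta_r) - log_bg[:, None]

        loglik = 0.0
        counts_l = np.zeros((4, k))
        counts_r = np.zeros((4, k))
        lam_acc = np.zeros(n_d)
        gamma_acc = 0.0

        for fwd, rev in seqs:
            per_strand = []
            log_terms = [np.array([math.log(max(1.0 - gamma, 1e-300))])]
            for codes in (fwd, rev):
                sl = _column_scores(codes, log_l, k)
                sr = _column_scores(codes, log_r, k)
                strand_rows = []
                for di, d in enumerate(spacers):
                    span = 2 * k + d
                    n_off = len(codes) - span + 1
                    if n_off <= 0 or lam[di] <= 0.0:
                        strand_rows.append(np.empty(0))
                        continue
                    site = sl[:n_off] + sr[k + d : k + d + n_off]
                    w = (
                        math.log(gamma)
                        + math.log(lam[di])
                        - math.log(2 * n_off)
                        + site
                    )
                    strand_rows.append(w)
                    log_terms.append(w)
                per_strand.append(strand_rows)
            flat = np.concatenate(log_terms)
            mx = float(np.max(flat))
            if not np.isfinite(mx):
                raise FloatingPointError(
                    f"non-finite likelihood at EM iteration {iteration}"
                )
            log_z = mx + math.log(float(np.sum(np.exp(flat - mx))))
            loglik += log_z

            gamma_resp = 0.0
            for strand_idx, codes in enumerate((fwd, rev)):
                for di in range(n_d):
                    w = per_strand[strand_idx][di]
                    if w.size == 0:
                        continue
                    resp = np.exp(w - log_z)
                    s = float(resp.sum())
                    if s <= 0.0:
                        continue
                    gamma_resp += s
                    lam_acc[di] += s
                    d = spacers[di]
                    for j in range(k):
                        col_l = codes[j : j + len(resp)]
                        np.add.at(counts_l[:, j], col_l[col_l >= 0], resp[col_l >= 0])
                        col_r = codes[k + d + j : k + d + j + len(resp)]
                        np.add.at(counts_r[:, j], col_r[col_r >= 0], resp[col_r >= 0])
            gamma_acc += gamma_resp

        obj = loglik + objective_terms(theta_l) + objective_terms(theta_r)
        objective_history.append(obj)
        if trace is not None:
            trace.append(obj)
        if obj + config.em_tolerance < prev_obj:
            # EM on the MAP objective cannot decrease; treat as numerical failure
            raise FloatingPointError(
                f"objective decreased at EM iteration {iteration}"
            )
        converged = obj - prev_obj < config.em_tolerance and iteration > 0
        prev_obj = obj
        if converged:
            break

        n = len(seqs)
        gamma = min(max(gamma_acc / n, 1e-9), 1.0 - 1e-9)
        if lam_acc.sum() > 0:
            lam = lam_acc / lam_acc.sum()
            lam = np.maximum(lam, 1e-12)
            lam /= lam.sum()
        theta_l = (counts_l + pc) / (counts_l + pc).sum(axis=0, keepdims=True)
        theta_r = (counts_r + pc) / (counts_r + pc).sum(axis=0, keepdims=True)

    best_d = spacers[int(np.argmax(lam))]
    return replace(
        seed_model,
        left_matrix=theta_l,
        right_matrix=theta_r,
        spacer_len=best_d,
        spacer_weights={d: float(l) for d, l in zip(spacers, lam)},
        site_prob=float(gamma),
        log_likelihood=float(objective_history[-1]),
    )


def discover_dyads(
    promoters: Sequence[Promoter],
    config: DyadConfig | None = None,
    n_starts: int = 5,
    refine: bool = True,
) -> DyadModel:
    """Full dyad discovery: enumeration plus multi-start EM refinement.

    Mismatch-tolerant counting cannot distinguish the true spacer from
    shifted near-duplicate alignments when the arms are homopolymer-like,
    so the top ``n_starts`` enumerated dyads each seed one EM run and the
    refined model with the highest penalised log-likelihood is returned
    (ties resolved by enumeration rank).  With ``refine=False`` the
    top-ranked enumerated model is returned unrefined.
    """
    config = config or DyadConfig()
    enumeration = enumerate_dyads(promoters, config)
    if not enumeration.models:
        raise ValueError("no supported dyads found")
    if not refine:
        return enumeration.models[0]
    best: DyadModel | None = None
    for seed_model in enumeration.models[:n_starts]:
        refined = refine_em(promoters, seed_model, config)
        if best is None or (
            refined.log_likelihood is not None
            and refined.log_likelihood > best.log_likelihood + 1e-9
        ):
            best = refined
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Consensus and export
# ---------------------------------------------------------------------------

_IUPAC_FROM_SET = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def _matrix_consensus(matrix: np.ndarray, include_threshold: float) -> str:
    letters = []
    for j in range(matrix.shape[1]):
        chosen = frozenset(
            b for i, b in enumerate(_BASES) if matrix[i, j] >= include_threshold
        )
        if not chosen:
            letters.append("N")
        else:
            letters.append(_IUPAC_FROM_SET[chosen])
    return "".join(letters)


def consensus_iupac(model: DyadModel, include_threshold: float = 0.3) -> str:
    """IUPAC consensus string of a dyad model: left arm, N-spacer, right arm.

    Per matrix column, the set of bases with frequency at or above the
    threshold maps to its IUPAC code; an empty set (no base reaches the
    threshold) and the full set both map to N.  Without matrices the
    consensus words themselves are used.
    """
    if model.left_matrix is not None and model.right_matrix is not None:
        left = _matrix_consensus(model.left_matrix, include_threshold)
        right = _matrix_consensus(model.right_matrix, include_threshold)
    else:
        left, right = model.left_arm, model.right_arm
    return left + "N" * model.spacer_len + right


def write_meme_minimal(
    model: DyadModel,
    path: str | Path,
    background: dict[str, float] | None = None,
    motif_name: str | None = None,
) -> None:
    """Export a refined dyad as a MEME minimal-format motif file.

    The dyad is flattened to a single position-probability matrix: left arm
    columns, spacer columns at background frequencies (point-estimate
    spacer length), right arm columns.
    """
    bg = background or {b: 0.25 for b in _BASES}
    if model.left_matrix is not None:
        left = model.left_matrix
        right = model.right_matrix
    else:
        left = np.zeros((4, model.arm_len))
        right = np.zeros((4, model.arm_len))
        for j, ch in enumerate(model.left_arm):
            left[_BASE_INDEX[ch], j] = 1.0
        for j, ch in enumerate(model.right_arm):
            right[_BASE_INDEX[ch], j] = 1.0
    spacer_col = np.array([[bg[b]] for b in _BASES])
    mat = np.hstack([left] + [spacer_col] * model.spacer_len + [right])
    name = motif_name or (
        f"dyad_{model.left_arm}_N{model.spacer_len}_{model.right_arm}"
    )
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.6f}" for b in _BASES) + "\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {mat.shape[1]} "
            f"nsites= {max(model.support, 1)} E= {model.p_value:.3e}\n"
        )
        for j in range(mat.shape[1]):
            fh.write(" ".join(f"{mat[i, j]:.6f}" for i in range(4)) + "\n")
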