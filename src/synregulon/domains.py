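"""Domain-architecture screen for CodY-like proteins.

CodY is the only characterised protein carrying both a ligand-sensing GAF
domain and a winged helix-turn-helix (wHTH) DNA-binding domain, so the
co-occurrence of the two Pfam domains on one protein is a sufficient
nomination criterion.  This module consumes HMMER3 per-domain tabular
output (``--domtblout``) and applies the two-domain filter at a strict
per-domain independent e-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Pfam accession of the CodY GAF (ligand-sensing) domain.
GAF_ACCESSION = "PF06018"
#: Pfam accession of the CodY winged helix-turn-helix DNA-binding domain.
WHTH_ACCESSION = "PF08222"


class DomtblParseError(ValueError):
    """Raised for malformed rows in a per-domain hit table."""


@dataclass(frozen=True)
class DomainHit:
    """One domain match on one protein (HMMER3 domtblout row)."""

    protein_id: str
    domain_accession: str
    i_evalue: float
    bitscore: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.i_evalue <= 0:
            raise ValueError(f"{self.protein_id}: i_evalue must be > 0")
        if self.env_start > self.env_end:
            raise ValueError(f"{self.protein_id}: env_start > env_end")


@dataclass(frozen=True)
class ScreenConfig:
    """Two-domain co-occurrence criterion.

    ``evalue_max`` is compared strictly (hit significant iff
    ``i_evalue < evalue_max``); the default 1e-3 is the conventional
    domain-presence threshold for this screen.
    """

    domain_a: str = GAF_ACCESSION
    domain_b: str = WHTH_ACCESSION
    evalue_max: float = 1e-3

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass(frozen=True)
class CodYCandidate:
    """A protein with significant hits to both screened domains."""

    protein_id: str
    hit_a: DomainHit
    hit_b: DomainHit


def _norm_accession(acc: str) -> str:
    # Pfam accessions in domtblout carry a version suffix (PF06018.9)
    return acc.split(".")[0]


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain tabular file into :class:`DomainHit` rows.

    Column positions follow the fixed domtblout layout: target name (0),
    query accession (4), independent e-value (12), domain bit score (13),
    envelope coordinates (19, 20).  Comment lines start with ``#``.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise DomtblParseError(
                    f"{path}: line {lineno}: expected >=22 columns, got {len(fields)}"
                )
            try:
                i_evalue = float(fields[12])
                bitscore = float(fields[13])
                env_start = int(fields[19])
                env_end = int(fields[20])
            except ValueError as exc:
                raise DomtblParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    domain_accession=fields[4],
                    i_evalue=i_evalue,
                    bitscore=bitscore,
                    env_start=env_start,
                    env_end=env_end,
                )
            )
    return hits


def screen_cooccurrence(
    hits: Iterable[DomainHit], config: ScreenConfig | None = None
) -> list[CodYCandidate]:
    """Nominate proteins carrying both screened domains.

    A protein qualifies iff it has at least one hit to each of the two
    domains with ``i_evalue`` strictly below ``evalue_max``.  Multiple hits
    to the same domain collapse to the best one (lowest e-value, ties by
    higher bit score).  Output is sorted by protein id.
    """
    config = config or ScreenConfig()
    want_a = _norm_accession(config.domain_a)
    want_b = _norm_accession(config.domain_b)
    best: dict[str, dict[str, DomainHit]] = {}
    for hit in hits:
        if hit.i_evalue >= config.evalue_max:
            continue
        acc = _norm_accession(hit.domain_accession)
        if acc not in (want_a, want_b):
            continue
        slot = best.setdefault(hit.protein_id, {})
        prev = slot.get(acc)
        if prev is None or (hit.i_evalue, -hit.bitscore) < (prev.i_evalue, -prev.bitscore):
            slot[acc] = hit
    out = []
    for pid in sorted(best):
        slot = best[pid]
        if want_a in slot and want_b in slot:
            out.append(CodYCandidate(protein_id=pid, hit_a=slot[want_a], hit_b=slot[want_b]))
    return out


def write_candidates_tsv(
    candidates: Iterable[CodYCandidate], path: str | Path
) -> None:
    rows = [
        (c.protein_id, c.hit_a.i_evalue, c.hit_b.i_evalue)
        for c in candidates
    ]
    pd.DataFrame(rows, columns=["protein_id", "gaf_evalue", "hth_evalue"]).to_csv(
        path, sep="\t", index=False
    )
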