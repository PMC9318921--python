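"""Functional enrichment of motif-positive loci and pipeline orchestration.

A gene counts toward its functional category when the promoter of its
operon leader carries a binding motif; per-category counts N per genome
are converted to enrichment scores log2(N + 1) and written as the heatmap
matrix (categories x genomes).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .domains import ScreenConfig, parse_domtblout, screen_cooccurrence, write_candidates_tsv
from .genome import (
    Genome,
    Operon,
    PromoterConfig,
    build_promoter_set,
    call_operons,
    read_fasta,
    read_gff3,
    write_promoters_tsv,
)
from .dyads import DyadConfig, DyadModel, discover_dyads, consensus_iupac
from .scan import (
    PromoterClass,
    SpacedPattern,
    classify_promoters,
    scan_iupac,
    scan_spaced,
)

logger = logging.getLogger(__name__)

UNANNOTATED = "-"


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot run; names the stage."""


def enrichment_score(n: int) -> float:
    """log2(N + 1) for a non-negative motif-positive gene count."""
    if n < 0:
        raise ValueError(f"count must be non-negative, got {n}")
    return math.log2(n + 1)


def load_annotations(path: str | Path) -> dict[str, str]:
    """Read a gene -> functional-category TSV (columns gene_id, category).

    A gene annotated twice is ambiguous input and raises ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    gene_col, cat_col = df.columns[:2]
    dup = df[gene_col][df[gene_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: genes annotated more than once: {sorted(set(dup))}")
    return dict(zip(df[gene_col], df[cat_col].fillna(UNANNOTATED)))


def tabulate_regulon(
    classes: Sequence[PromoterClass],
    operons: Sequence[Operon],
    annotations: Mapping[str, str],
    genome_label: str = "genome",
) -> pd.DataFrame:
    """Per-category counts N of motif-positive genes for one genome.

    A gene counts toward its category iff its operon leader's promoter has
    a category other than "none"; genes without an annotation pool under
    "-".  Annotations for genes absent from every operon trigger a warning
    and are skipped.
    """
    known_genes = {g for op in operons for g in op.gene_ids}
    unknown = sorted(set(annotations) - known_genes)
    if unknown:
        logger.warning(
            "%d annotated gene(s) not present in any operon (e.g. %s); skipped",
            len(unknown),
            unknown[:3],
        )
    positive_leaders = {c.locus_id for c in classes if c.category != "none"}
    counts: dict[str, int] = {}
    for op in operons:
        if op.leader not in positive_leaders:
            continue
        for gene in op.gene_ids:
            cat = annotations.get(gene, UNANNOTATED) or UNANNOTATED
            counts[cat] = counts.get(cat, 0) + 1
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=[genome_label])
    return frame.sort_index()


@dataclass
class EnrichmentMatrix:
    """Category x genome counts with log2(N + 1) scores."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.sort_index().sort_index(axis=1)

    @property
    def scores(self) -> pd.DataFrame:
        return self.counts.map(lambda n: enrichment_score(int(n)))

    @classmethod
    def from_tables(cls, tables: Sequence[pd.DataFrame]) -> "EnrichmentMatrix":
        """Combine per-genome count tables into one matrix (missing = 0)."""
        if not tables:
            return cls(counts=pd.DataFrame())
        merged = pd.concat(tables, axis=1).fillna(0).astype(int)
        return cls(counts=merged)


def write_matrix(
    matrix: EnrichmentMatrix,
    path: str | Path,
    heatmap_path: str | Path | None = None,
) -> None:
    """Write the enrichment-score TSV (6-decimal cells, sorted axes).

    The TSV is the tested artifact; the optional heatmap PNG is a
    convenience rendering.
    """
    scores = matrix.scores
    scores.to_csv(path, sep="\t", float_format="%.6f", index_label="category")
    if heatmap_path is not None and not scores.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.5 * scores.shape[1], 1 + 0.4 * scores.shape[0])
        )
        im = ax.imshow(scores.values, cmap="viridis", aspect="auto")
        ax.set_xticks(range(scores.shape[1]), scores.columns, rotation=90)
        ax.set_yticks(range(scores.shape[0]), scores.index)
        fig.colorbar(im, ax=ax, label="log2(N + 1)")
        fig.tight_layout()
        fig.savefig(heatmap_path, dpi=120)
        plt.close(fig)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="category")


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def _require(config: Mapping, key: str, stage: str):
    if key not in config or config[key] is None:
        raise PipelineError(f"stage {stage!r}: missing config key {key!r}")
    return config[key]


def run_pipeline(config: Mapping | str | Path, outdir: str | Path | None = None) -> dict:
    """Run screen -> promoters -> dyad discovery -> scan -> enrichment.

    ``config`` is a mapping or a YAML file path.  Outputs are written to
    ``outdir`` (or the config's ``outdir``): candidates.tsv,
    promoters.tsv, motif.json, hits.tsv, classes.tsv, matrix.tsv plus a
    provenance.json recording version, seed and parameters.  Identical
    configurations produce bit-identical outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    outdir = Path(outdir or config.get("outdir") or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    artifacts: dict[str, Path] = {}

    # -- domain screen ------------------------------------------------------
    domtbl = config.get("domtbl")
    if domtbl:
        screen_cfg = ScreenConfig(
            domain_a=config.get("domain_a", ScreenConfig.domain_a),
            domain_b=config.get("domain_b", ScreenConfig.domain_b),
            evalue_max=float(config.get("evalue_max", ScreenConfig.evalue_max)),
        )
        candidates = screen_cooccurrence(parse_domtblout(domtbl), screen_cfg)
        artifacts["candidates"] = outdir / "candidates.tsv"
        write_candidates_tsv(candidates, artifacts["candidates"])

    # -- promoters ----------------------------------------------------------
    fasta = _require(config, "fasta", "extract-promoters")
    gff = _require(config, "gff", "extract-promoters")
    pcfg_raw = config.get("promoter", {})
    pconfig = PromoterConfig(
        window=int(pcfg_raw.get("window", 400)),
        operon_max_gap=int(pcfg_raw.get("max_gap", 50)),
        clip_at_upstream_gene=bool(pcfg_raw.get("clip", True)),
    )
    genome = read_gff3(gff, read_fasta(fasta))
    operons = call_operons(genome, pconfig)
    promoters = build_promoter_set(genome, pconfig)
    artifacts["promoters"] = outdir / "promoters.tsv"
    write_promoters_tsv(promoters, artifacts["promoters"])
    if not promoters:
        raise PipelineError("stage 'discover-dyads': no promoters extracted")

    # -- dyad discovery -----------------------------------------------------
    dcfg_raw = config.get("discovery", {})
    dconfig = DyadConfig(
        arm_len=int(dcfg_raw.get("arm_len", 6)),
        spacer_min=int(dcfg_raw.get("spacer_min", 0)),
        spacer_max=int(dcfg_raw.get("spacer_max", 30)),
        palindrome_mismatch_max=int(dcfg_raw.get("palindrome_mismatch_max", 2)),
        seed=seed,
    )
    try:
        top = discover_dyads(
            promoters, dconfig, refine=bool(dcfg_raw.get("refine", True))
        )
    except ValueError as exc:
        raise PipelineError(f"stage 'discover-dyads': {exc}") from exc
    artifacts["motif"] = outdir / "motif.json"
    top.save_json(artifacts["motif"])

    # -- scan and classify --------------------------------------------------
    scfg = config.get("scan", {})
    canonical = SpacedPattern.contiguous(
        "canonical-codY-box",
        scfg.get("canonical", "AATTTTCWGAAAATT"),
        max_mismatch=int(scfg.get("max_mismatch", 1)),
    )
    extended = SpacedPattern(
        pattern_id="extended-palindrome",
        left=top.left_arm,
        spacer_lens=(top.spacer_len,),
        right=top.right_arm,
        max_mismatch=int(scfg.get("extended_max_mismatch", dconfig.palindrome_mismatch_max)),
    )
    hit_rows = []
    for p in promoters:
        for h in scan_iupac(p.sequence, canonical, sequence_id=p.locus_id):
            hit_rows.append(
                (h.sequence_id, h.offset, h.strand, h.pattern_id, h.mismatches)
            )
        for h in scan_spaced(p.sequence, extended, sequence_id=p.locus_id):
            hit_rows.append(
                (h.sequence_id, h.offset, h.strand, h.pattern_id, h.mismatches)
            )
    artifacts["hits"] = outdir / "hits.tsv"
    pd.DataFrame(
        sorted(hit_rows),
        columns=["sequence_id", "offset", "strand", "pattern", "mismatches"],
    ).to_csv(artifacts["hits"], sep="\t", index=False)

    classes, summary = classify_promoters(
        promoters,
        canonical,
        extended,
        operons=operons,
        n_genes=len(genome.genes),
    )
    artifacts["classes"] = outdir / "classes.tsv"
    pd.DataFrame(
        [(c.locus_id, c.has_canonical, c.has_extended, c.category) for c in classes],
        columns=["locus_id", "has_canonical", "has_extended", "category"],
    ).to_csv(artifacts["classes"], sep="\t", index=False)

    # -- enrichment ---------------------------------------------------------
    annotations_path = config.get("annotations")
    annotations = load_annotations(annotations_path) if annotations_path else {}
    label = config.get("genome_label", "genome")
    table = tabulate_regulon(classes, operons, annotations, genome_label=label)
    matrix = EnrichmentMatrix.from_tables([table]) if not table.empty else EnrichmentMatrix(
        counts=pd.DataFrame(columns=[label], dtype=int)
    )
    artifacts["matrix"] = outdir / "matrix.tsv"
    write_matrix(matrix, artifacts["matrix"])

    provenance = {
        "version": __version__,
        "seed": seed,
        "promoter_config": {
            "window": pconfig.window,
            "operon_max_gap": pconfig.operon_max_gap,
            "clip_at_upstream_gene": pconfig.clip_at_upstream_gene,
        },
        "discovery_config": {
            "arm_len": dconfig.arm_len,
            "spacer_min": dconfig.spacer_min,
            "spacer_max": dconfig.spacer_max,
            "palindrome_mismatch_max": dconfig.palindrome_mismatch_max,
        },
        "top_motif": consensus_iupac(top),
        "summary": summary.to_dict(),
    }
    artifacts["provenance"] = outdir / "provenance.json"
    with open(artifacts["provenance"], "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return {
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "summary": summary.to_dict(),
        "top_motif": top,
    }
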