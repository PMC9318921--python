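import numpy as np
import pytest
from hypothesis import settings

import synregulon as sr

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def consensus36() -> str:
    """The 36-base Synergistes/Cloacibacillus promoter consensus."""
    return sr.SYNERGISTES_CONSENSUS


@pytest.fixture
def tiny_genome() -> sr.Genome:
    """Single 1-kb contig with two operons on opposite strands.

    Layout (0-based half-open):
      geneA [400, 700) +   geneB [710, 800) +   (gap 10 -> one operon, leader A)
      geneC [850, 950) -                         (singleton, leader C)
    """
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    genes = [
        sr.GeneAnnotation("geneA", "c1", 400, 700, "+"),
        sr.GeneAnnotation("geneB", "c1", 710, 800, "+"),
        sr.GeneAnnotation("geneC", "c1", 850, 950, "-"),
    ]
    return sr.Genome(contigs={"c1": seq}, genes=genes)


@pytest.fixture
def planted_promoters():
    """20 background promoters (GC 0.5) each planted with AAAATT-N15-AATTTT."""
    spec = sr.SyntheticSpec(n_promoters=20, length=400, gc=0.5, seed=31)
    promoters = sr.gen_background(spec)
    return sr.plant_dyad(promoters, ("AAAATT", 15, "AATTTT"), 1.0, seed=32)
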