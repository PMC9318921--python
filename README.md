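# synregulon

Inference of CodY-like regulons in the bacterial phylum Synergistetes.

CodY, the master nutritional regulator of Firmicutes, couples a
ligand-sensing GAF domain to a winged helix-turn-helix (wHTH) DNA-binding
domain and represses targets through the palindromic 15-bp CodY box
`5'-AATTTTCWGAAAATT`. Because CodY is the only characterised protein with
that domain pair, GAF + wHTH co-occurrence nominates CodY-like regulators
in other phyla. In Synergistetes the candidate operators are *spaced
dyads* — an AT-rich arm, an unconstrained spacer of d bases, and the
arm's (near) reverse complement, `ARM-N_d-rc(ARM)` — such as the
genus-level motifs `AATATT-N21-AAAATA`, `ATTTTY-N14-AAAAAT` and
`WWTTTT-N12-ATAATT`, and the 36-base *Synergistes*/*Cloacibacillus*
consensus `AATTTTCTTAAAATTTCSCTTGATATTTACAATTTT`, whose three AT-rich
arms form both a canonical CodY box and an `AAAATT-N15-AATTTT` inverted
repeat.

The package provides, as a plain Python library:

* **domain screen** — HMMER3 `domtblout` parsing and the two-domain
  (GAF + wHTH, e < 1e-3) co-occurrence filter;
* **genome I/O** — FASTA/GFF3 input, a same-strand distance-based operon
  caller, and operon-leader promoter extraction (400-bp windows);
* **dyad discovery** — exhaustive (arm, spacer) enumeration with exact
  binomial significance against an order-0 null, plus multi-start
  ZOOPS-EM refinement into frequency matrices, spacer-length weights and
  an IUPAC consensus;
* **motif scanning** — IUPAC patterns with mismatches, spaced two-arm
  patterns, and FIMO-style PWM scanning with exact p-values from a
  dynamic programme; promoter classification into canonical / extended /
  both / none;
* **enrichment** — per-category counts of motif-positive genes and the
  `log2(N + 1)` heatmap matrix;
* **synthetic data** — seeded generators for every input above, with
  truth tables, so the whole pipeline is testable offline.

It is intended for computational microbiologists studying regulon
evolution outside model phyla, and as a reference implementation of
spaced-palindrome discovery with explicit, testable statistics.

## Worked example

```python
import synregulon as sr
from synregulon.dyads import discover_dyads

# the reported consensus: three AT-rich arms, two palindromic pairs
occ = sr.find_arms(sr.SYNERGISTES_CONSENSUS, {"AATTTT", "AAAATT"})
print([(o.offset, o.word) for o in occ])
# [(0, 'AATTTT'), (9, 'AAAATT'), (30, 'AATTTT')]
pairs = sr.pair_arms(occ)
print([(p.left.offset, p.right.offset, p.spacer) for p in pairs])
# [(0, 9, 3), (9, 30, 15)]   <- inner dyad N3, outer dyad N15

# recover a planted genus dyad from 20 synthetic 400-bp promoters
spec = sr.SyntheticSpec(n_promoters=20, length=400, gc=0.5, seed=11)
promoters, truth = sr.plant_dyad(
    sr.gen_background(spec), ("AATATT", 21, "AAAATA"), fraction=1.0, seed=12
)
best = discover_dyads(promoters)
print(best.spacer_len, best.support, sr.consensus_iupac(best))
# 21 20 TATTTTNNNNNNNNNNNNNNNNNNNNNAATATT
```

The arm offsets 0/9/30 partition the 36-base consensus into its three
AT-rich arms; the outer pair's spacer of 15 is the extended
`AAAATT-N15-AATTTT` palindrome, and the recovered spacer 21 on the
synthetic set equals the planted truth (the arms are reported in the
reverse-strand orientation, `TATTTT-N21-AATATT` being the reverse
complement of the planted `AATATT-N21-AAAATA`). Longer narrative walk-throughs of
each capability live in `examples/`, and a YAML-driven end-to-end run
(`synregulon run --config pipeline.yaml`) chains screen → promoters →
discovery → scan → enrichment with deterministic artifacts.

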