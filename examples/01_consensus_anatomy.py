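"""Anatomy of the Synergistes/Cloacibacillus promoter consensus.

Locates the three AT-rich arms of the reported 36-base consensus, pairs
them into palindromic dyads, and shows that the same string carries both
a canonical CodY box (one mismatch from AATTTTCWGAAAATT) and the extended
AAAATT-N15-AATTTT inverted repeat.
"""

import synregulon as sr

consensus = sr.SYNERGISTES_CONSENSUS
print(f"consensus ({len(consensus)} nt): {consensus}\n")

occurrences = sr.find_arms(consensus, {"AATTTT", "AAAATT"})
print("AT-rich arm occurrences:")
for occ in occurrences:
    print(f"  offset {occ.offset:2d}  {occ.word}  ({occ.sense})")

pairs = sr.pair_arms(occurrences)
print("\nreverse-complement arm pairs (dyads):")
for pair in pairs:
    print(
        f"  {pair.left.word} @ {pair.left.offset}  ...N{pair.spacer}...  "
        f"{pair.right.word} @ {pair.right.offset}"
    )

box = sr.SpacedPattern.contiguous("codY-box", sr.CANONICAL_CODY_BOX, max_mismatch=1)
hit = [h for h in sr.scan_iupac(consensus, box) if h.strand == "+"][0]
print(
    f"\ncanonical CodY box {sr.CANONICAL_CODY_BOX} matches at offset "
    f"{hit.offset} with {hit.mismatches} mismatch"
)

extended = sr.SpacedPattern(
    pattern_id="extended", left="AAAATT", spacer_lens=(15,), right="AATTTT"
)
ext_hit = [h for h in sr.scan_spaced(consensus, extended) if h.strand == "+"][0]
print(f"extended palindrome AAAATT-N15-AATTTT matches at offset {ext_hit.offset}")

print(
    "\nThe two dyads share the middle arm: the inner pair (spacer 3) is the"
    "\ncanonical box, the outer pair (spacer 15) is the extended palindrome."
)
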