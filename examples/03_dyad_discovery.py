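"""Recover a planted genus dyad from synthetic promoters.

Builds 20 background promoters (400 bp, GC 0.50), plants the
Thermanaerovibrio-style dyad AATATT-N21-AAAATA in every one, and runs the
full discovery chain: enumeration with binomial significance, then
multi-start ZOOPS-EM refinement.  The recovered spacer length equals the
planted 21; the arms may come out in either strand orientation.
"""

import synregulon as sr
from synregulon.dyads import discover_dyads

spec = sr.SyntheticSpec(n_promoters=20, length=400, gc=0.5, seed=11)
promoters = sr.gen_background(spec)
promoters, truth = sr.plant_dyad(promoters, ("AATATT", 21, "AAAATA"), 1.0, seed=12)
print(f"planted AATATT-N21-AAAATA in {int(truth.planted.sum())}/20 promoters")

enumeration = sr.enumerate_dyads(promoters)
print(f"\ntested {enumeration.n_hypotheses} (arm, spacer) hypotheses; top 3:")
for m in enumeration.models[:3]:
    print(
        f"  {m.left_arm}-N{m.spacer_len}-{m.right_arm}: "
        f"support {m.support}/{m.n_promoters}, p = {m.p_value:.2e}"
    )

best = discover_dyads(promoters)
print(f"\nafter multi-start EM refinement:")
print(f"  consensus       : {sr.consensus_iupac(best)}")
print(f"  spacer estimate : {best.spacer_len} (planted: 21)")
print(f"  site probability: {best.site_prob:.2f}")
print(
    "\nThe EM's spacer-weight distribution resolves the shift degeneracy of"
    "\nmismatch-tolerant counting, pinning the spacer to the planted value."
)
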