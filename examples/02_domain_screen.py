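"""Two-domain screen for CodY-like proteins on a synthetic hit table.

Generates a HMMER3-style per-domain table with known positives, applies
the GAF + wHTH co-occurrence filter at e < 1e-3 and compares the result
with the generator's truth list.
"""

import tempfile
from pathlib import Path

import synregulon as sr

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "hits.tbl"
    _, truth = sr.gen_domtblout_fixture(
        n_proteins=25, n_with_both=4, n_with_one=8, seed=5, path=path
    )
    hits = sr.parse_domtblout(path)
    candidates = sr.screen_cooccurrence(hits)

print(f"parsed {len(hits)} domain hits over 25 proteins")
print("candidates (both GAF and wHTH significant at e < 1e-3):")
for c in candidates:
    print(
        f"  {c.protein_id}: GAF e={c.hit_a.i_evalue:.2e}, "
        f"wHTH e={c.hit_b.i_evalue:.2e}"
    )
print(f"truth list from the generator: {truth}")
print("match:", [c.protein_id for c in candidates] == truth)
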