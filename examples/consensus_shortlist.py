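"""Combine HSP and ASP shortlists into prioritization categories.

Solvents short-listed by both similarity models are the strongest
substitution candidates; solvents picked by neither serve as negative
controls.  This script categorizes the bundled published top-12 lists for
chloroform replacement.
"""

from collections import Counter

from solvselect import Category, categorize
from solvselect.datasets import load_screening_shortlists

table = load_screening_shortlists()
hsp = list(table[table.model == "hsp"]["name"])
asp = list(table[table.model == "asp"]["name"])
universe = sorted(set(hsp) | set(asp))

records = categorize(hsp, asp, universe)
counts = Counter(r.category for r in records)
print(f"universe of short-listed solvents: {len(universe)}")
for category in Category:
    print(f"  {category.value:8s}: {counts[category]}")

both = [r.solvent_name for r in records if r.category is Category.BOTH]
print(f"\nprioritized by both models: {', '.join(both)}")
print("These four dual hits (DCM, thiophene, tetrahydrofuran, fluorobenzene)")
print("anchor the experimental test set; aromatic and chemotype exclusions")
print("are then applied via apply_practical_rules().")
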