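"""Rank candidate solvents by Hansen distance to chloroform.

The Hansen distance Ra (MPa^0.5) measures how similar two solvents are in
dispersion / polar / hydrogen-bonding space; candidates with small Ra to a
reference are likely substitutes.  This script scores the bundled handbook
parameter table against chloroform and applies the conventional Ra < 5 cut.
"""

from solvselect import Catalog, SolventRecord, rank_by_hsp, select_by_ra
from solvselect.datasets import load_hansen_reference

reference_table = load_hansen_reference()
catalog = Catalog(
    [SolventRecord(name=name, hansen=params) for name, params in reference_table.items()]
)

ranking = rank_by_hsp(catalog, "chloroform")
print("Hansen distance to chloroform (MPa^0.5):")
for result in ranking.results:
    print(f"  {result.rank:2d}. {result.solvent_name:28s} Ra = {result.ra:.2f}")

shortlist = select_by_ra(ranking, ra_max=5.0)
print(f"\ncandidates with Ra < 5: {', '.join(shortlist)}")
print("Smaller Ra means a closer match to chloroform's solubility behaviour;")
print("cyclopentyl methyl ether (2.87) and 2-methyltetrahydrofuran (2.97) are")
print("the closest non-chlorinated candidates.")
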