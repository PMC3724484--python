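"""The four evaluation criteria on a worked micro-example.

Reference complexes R1={a,b,c}, R2={c,d} (overlapping at c) are compared
with the prediction P1={a,b}, P2={c,d}.  All four criteria are computed
from the contingency table of shared-protein counts.
"""

from bmfcluster import ComplexSet, contingency, evaluate

reference = ComplexSet.from_sets([{"a", "b", "c"}, {"c", "d"}], names=["R1", "R2"])
predicted = ComplexSet.from_sets([{"a", "b"}, {"c", "d"}], names=["P1", "P2"])

ct = contingency(reference, predicted)
print("contingency table T (rows: reference, columns: prediction):")
print(ct.T)

report = evaluate(reference, predicted)
print(f"Sn  = {report.sn:.4f}   coverage: each reference complex's best-matching cluster")
print(f"PPV = {report.ppv:.4f}   purity: each cluster's dominant reference complex")
print(f"Acc = {report.acc:.4f}   geometric mean of Sn and PPV")
print(f"Sep = {report.sep:.4f}   two-way correspondence of the doubly normalized overlaps")
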