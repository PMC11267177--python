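"""Compare two comorbidity profiles with the four similarity indices.

Group A spreads its mass over two codes; group B concentrates on one.
JI sees only set overlap; PJI weighs the overlap by the groups' proportions;
OPJI/APJI further multiply each code's mass by an association weight.
"""

from pjindex import GroupProfile, jaccard, pji, weighted_pji

a = GroupProfile({"414": 0.5, "250": 0.5})   # coronary disease + diabetes
b = GroupProfile({"414": 1.0})               # coronary disease only

print("JI  =", round(jaccard(a.support, b.support).value, 4))
print("PJI =", round(pji(a, b).value, 4))

# give coronary disease twice the association weight of diabetes
w = {"414": 2.0, "250": 1.0}
print("OPJI-style weighted =", round(weighted_pji(a, b, w).value, 4))

print()
print("JI 0.5: one of the two union codes is shared.")
print("PJI 0.6: the shared code carries q=(0.5+1.0)/2=0.75 of 1.25 total mass.")
print("Weighted 0.75: up-weighting the shared code raises the similarity further.")
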