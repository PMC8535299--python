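"""Combine two bodies of evidence with Dempster's rule.

Two sources each distribute belief over the hypotheses {diabetic, healthy}.
The conflict coefficient K measures how much paired belief falls on
incompatible hypotheses; the combined mass reallocates the compatible
products and renormalizes by 1 - K.
"""

from diabfuse import MassFunction, combine_bpa, conflict

frame = {"diabetic", "healthy"}
source_a = MassFunction(frame, {
    frozenset({"diabetic"}): 0.6,
    frozenset({"healthy"}): 0.3,
    frozenset(frame): 0.1,          # undecided mass
})
source_b = MassFunction(frame, {
    frozenset({"diabetic"}): 0.7,
    frozenset({"healthy"}): 0.2,
    frozenset(frame): 0.1,
})

k = conflict(source_a, source_b)
combined = combine_bpa(source_a, source_b)

print(f"conflict K = {k:.4f}")
for subset, mass in sorted(combined.masses.items(), key=lambda kv: sorted(kv[0])):
    print(f"m({{{', '.join(sorted(subset))}}}) = {mass:.4f}")
# K is the probability the two sources back mutually exclusive hypotheses;
# after combination most mass concentrates on 'diabetic' because both
# sources lean that way and their agreement reinforces.
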