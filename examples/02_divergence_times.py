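"""Neutral divergence times from pairwise differences per site.

T = K / (2 r) with r = 3.0e-9 substitutions/site/generation and one
generation per year: the conservative molecular-clock arithmetic used to
date TE divergences. K values here are the kind of pairwise p-distances a
group-mean distance table produces.
"""

from httdetect.distances import divergence_time, identity_to_time

for K, note in [
    (0.20, "the 80% identity floor across all retained copies"),
    (0.0751, "the most divergent pair inside a focal clade"),
    (0.00983, "the most divergent pair of a recent, near-identical clade"),
]:
    est = divergence_time(K)
    print(f"K = {K:<8.5f} -> T = {est.T_years / 1e6:6.2f} million years "
          f"({note})")

print()
t80 = identity_to_time(0.80)
print(f"identity floor 80%  -> earliest origin ~{t80 / 1e6:.1f} MY ago")
t9995 = identity_to_time(0.9995)
print(f"identity > 99.95%   -> origin within ~{t9995:,.0f} years")
# A TE clade whose copies are >99.95% identical across species that split
# hundreds of millions of years ago cannot have been inherited vertically.
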