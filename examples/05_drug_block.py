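"""Antiarrhythmic drug block: 50% reduction of the rapid delayed rectifier.

Paces the cAF-remodeled model to steady state, halves gKr (emulating an
I_Kr-blocking drug), repeats the full stimulus protocol, and reports the AP
prolongation.  I_Kr is a late repolarizing current, so blocking it restores
longer, SR-like action potentials.
"""

from pomcal import ap_model

theta = ap_model.caf_adjusted_baseline()
pre = ap_model.forward_map(theta)
post = ap_model.forward_map(ap_model.apply_drug_block(theta, "gKr", 0.5))

print(f"cAF model APD90 before I_Kr block: {pre.APD90:7.2f} ms")
print(f"cAF model APD90 after 50% block:   {post.APD90:7.2f} ms")
print(f"prolongation:                      {post.APD90 - pre.APD90:7.2f} ms")
print(f"post-block RMP: {post.RMP:.2f} mV "
      "(members above -60 mV would be flagged as unrealistic)")
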