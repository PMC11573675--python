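"""Build a session protocol and inspect the product-graph structure.

The transfer phase combines a 4-cycle and a 6-cycle moving in lockstep:
24 compound states split into two disconnected 12-state components, and
the repeated 12-image sequence exposes exactly 12 of the 24 possible
ordered transitions — the other half belongs to the held-out component
probed only by inference questions.
"""

from srcompose import build_protocol, product_components

protocol = build_protocol("prior4cycle", seed=7)

f4, f6 = protocol.transfer.f1, protocol.transfer.f2
components = product_components(f4, f6)
print("transfer component sizes:", [len(c) for c in components])

observed = set(protocol.transition_pairs("transfer"))
print("distinct transitions shown in transfer:", len(observed), "of 24")

seq = protocol.transfer.sequences[0]
print("transfer sequence:", " -> ".join(s.label(f4, f6) for s in seq[:6]), "...")

exp, inf = protocol.transfer.probes[0]
print(
    f"trial-1 experience probe: cue {exp.cue.label(f4, f6)}, "
    f"correct {exp.option_correct.label(f4, f6)}, "
    f"lure {exp.option_lure.label(f4, f6)} (probed size {exp.probed_size})"
)
print(
    f"trial-1 inference probe:  cue {inf.cue.label(f4, f6)} "
    f"(held-out component, probed size {inf.probed_size})"
)
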