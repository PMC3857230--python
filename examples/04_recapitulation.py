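"""How robust are communities to the edge-significance threshold?

Thresholding at FDR <= 0.01% keeps a subnetwork of the FDR <= 1% network.
If community structure is robust to the extra "noisy" edges of the
lenient network, each stringent community should land almost wholly
inside a single lenient community.
"""

from chromnet import (
    RosetteSpec, generate, build_network, louvain, filter_small, recapitulation,
)

fragments, records, _ = generate(RosetteSpec(seed=0))
lenient = build_network(records, fragments, cls="inter", fdr_threshold=0.01)
stringent = build_network(records, fragments, cls="inter", fdr_threshold=0.0001)
print(f"lenient network: {lenient.n_nodes} nodes / {lenient.m} edges; "
      f"stringent subnetwork: {stringent.n_nodes} / {stringent.m}")

assignments = []
for net in (stringent, lenient):
    filtered = filter_small(louvain(net, seed=1).final, min_size=10)
    assignments.append(
        {u: c for c, nodes in filtered.communities.items() for u in nodes}
    )
result = recapitulation(*assignments)
for c, r in result.per_community.items():
    print(f"  stringent community {c}: {100 * r:.0f}% inside one lenient community")
print(f"mean recapitulation: {100 * result.mean_recap:.0f}%")
# Values near 100% mean the coarse community structure is insensitive to
# the significance threshold chosen for edges.
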