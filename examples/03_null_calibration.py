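"""Is the observed modularity larger than random graphs can produce?

Partitions of random graphs can score surprisingly high modularity, so a
raw Q value means nothing on its own. The observed partition is compared
to G(n, m) graphs of equal order and size, each partitioned the same
way, and summarised as a standard score.
"""

from chromnet import RosetteSpec, generate, build_network, modularity_zscore

fragments, records, _ = generate(RosetteSpec(seed=0))
net = build_network(records, fragments, cls="inter", fdr_threshold=0.01)
result = modularity_zscore(net, n_replicates=200, seed=1)
print(f"observed Q = {result.observed_q:.3f}")
print(f"null Q over {len(result.null_qs)} G(n,m) replicates: "
      f"{result.null_mean:.3f} +/- {result.null_sd:.3f}")
print(f"standard score Z = {result.z:.2f}, empirical p = {result.empirical_p:.4g}")
# Z far above ~3 means the community structure cannot be explained by
# edge density alone; empirical p is the fraction of nulls scoring higher.
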