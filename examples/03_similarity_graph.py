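"""Build the directed similarity graph and find Leiden communities.

Each (dataset, group) node keeps its single best outward edge per
external dataset; communities then aggregate mutually similar groups
across datasets.
"""

from clusterfold import (
    SimConfig,
    build_graph,
    compare_datasets,
    find_communities,
    intersect_features,
    simulate_paired_datasets,
    stabilized_fc_frames,
)

cfg = SimConfig(
    n_datasets=2, n_groups=4, cells_per_group=80, n_features=400,
    n_markers_per_group=10, marker_log2fc=3.0, seed=5,
)
datasets, _ = simulate_paired_datasets(cfg)
space = intersect_features(datasets)
frames = {
    ds.name: stabilized_fc_frames(ds, space, n_subsamples=8, seed=6)
    for ds in datasets
}
records = compare_datasets(frames)

graph = build_graph(records, top_n=1)
graph.community_of = find_communities(graph, resolution=1.0, seed=0)

print(f"{len(graph.nodes)} nodes, {len(graph.edges)} directed edges")
print("\nedges (source -> target, similarity):")
for (sd, sg), (td, tg), w in graph.edges:
    print(f"  {sd}:{sg} -> {td}:{tg}   {w:+.2f}")
print("\ncommunities (matched groups land together):")
for node in graph.nodes:
    print(f"  {node[0]}:{node[1]}  community {graph.community_of[node]}")
# With top_n=1 every node has exactly one outward edge per external
# dataset; each community should pair a group with its counterpart.
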