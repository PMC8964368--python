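"""Hub analysis of a module-induced PPI subnetwork.

The module's genes induce a subgraph of the STRING-style network; nodes are
ranked by degree (closeness breaks ties) and the top 15 are hubs.  Coverage
states how much of the module the hubs reach directly: the fraction of
input genes adjacent to a hub, and the fraction of edges touching a hub.
"""

import cochnet as cn

matrix, design, _, graph, truth = cn.generate_bundle(cn.SimConfig())

module = "planted_1"
genes = truth.module_members(module)
table, report, missing = cn.module_hub_analysis(graph, genes, k=15)

print(f"module {module}: {len(genes)} genes, "
      f"{len(genes) - len(missing)} present in the PPI network")
print(f"top hubs by degree: {report.hubs[:5]} ...")
print(f"planted hubs {truth.hub_genes[module]} recovered: "
      f"{set(truth.hub_genes[module]) <= set(report.hubs)}")
print(f"gene coverage: {report.covered_genes}/{report.gene_total} "
      f"({100 * report.gene_coverage:.1f}%) module genes adjacent to a hub")
print(f"edge coverage: {report.covered_edges}/{report.edge_total} "
      f"({100 * report.edge_coverage:.1f}%) interactions involve a hub")
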