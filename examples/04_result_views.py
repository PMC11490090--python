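"""Plot-ready views of an enrichment result.

From one ORA run: the ranked significant sub-table (lollipop chart data),
the enrichment network (nodes = significant entries, edges weighted by
shared target genes) and the gene-by-entry membership matrix (heatmap
data).
"""

from setenrich import (
    build_graph,
    build_membership,
    list_to_collection,
    ora_analysis,
    significant_table,
)

collection = list_to_collection(
    {
        "TF_A": ["g00", "g01", "g02", "g03"],
        "TF_B": ["g02", "g03", "g04", "g05"],
        "TF_C": ["g30", "g31", "g32"],
    }
)
background = [f"g{i:02d}" for i in range(40)]
target = ["g00", "g01", "g02", "g03", "g04", "g05"]

table, query = ora_analysis(collection, target, background,
                            resamples=5000, seed=1)

sig = significant_table(table, column="efdr", alpha=0.05)
print("significant entries (efdr < 0.05):")
print(sig[["ontology_id", "k", "K", "efdr"]].to_string(index=False))

graph = build_graph(table, query, alpha=0.05)
print("\nenrichment network edges (weight = shared target genes):")
for a, b, d in graph.edges(data=True):
    print(f"  {a} -- {b}  weight={d['weight']}")

mm = build_membership(table, query, alpha=0.05)
print("\nmembership matrix (rows annotated with eFDR):")
print(mm.matrix.to_string())
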