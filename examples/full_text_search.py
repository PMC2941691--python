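"""Full-text search over genes and T/Cs with the bespoke inverted index.

Indexes a handful of documents and shows OR-semantics keyword queries,
including the hyphen-compound case where the query 'PR1' must reach the
annotation spelling 'PR-1'.
"""

from microtc.search import SearchDoc, build_index

docs = [
    SearchDoc("gene:AT2G14610", "gene",
              {"gene_identifier": "AT2G14610", "gene_symbol": "PR-1",
               "gene_annotation": "pathogenesis-related protein 1"}),
    SearchDoc("gene:AT3G57260", "gene",
              {"gene_identifier": "AT3G57260", "gene_symbol": "PR-2",
               "gene_annotation": "beta-1,3-glucanase, SAR response"}),
    SearchDoc("tc:cold12", "tc", {"tc_name": "Cold treatment 12 hr vs none"}),
    SearchDoc("tc:cold6", "tc", {"tc_name": "Cold treatment 6 hr vs none"}),
    SearchDoc("tc:pst16", "tc", {"tc_name": "16 hr Pseudomonas infection"}),
]
idx = build_index(docs)

for q in ("PR1 PR2", "cold", "infection", "pseudo"):
    hits = idx.query(q, substring=(q == "pseudo"))
    shown = ", ".join(f"{d} ({s:.2f})" for d, s in hits)
    print(f"query {q!r:<12} -> {shown or '(no hits)'}")
# 'PR1 PR2' ORs its terms and hits both genes through the joined-compound
# tokens; 'pseudo' only matches in substring mode.
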