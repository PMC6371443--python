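"""Hypergeometric GO over-representation on a planted annotation universe.

Builds a 1000-gene universe with 50 random terms, three of which are
over-represented fivefold in a 100-gene query, then ranks terms by the
one-sided hypergeometric p-value P(X >= k).
"""

import panicle as pn

annotation, query, truth = pn.simulate_annotation(
    universe_size=1000, n_terms=50, term_size=20, enriched_terms=3,
    query_size=100, enrichment_factor=5.0, seed=7)
print(f"universe: {len(annotation.universe)} annotated genes; "
      f"query: {len(query)} genes; planted terms: {sorted(truth.enriched_terms)}")

result = pn.enrich_terms(query, annotation, min_overlap=2)
top = result.table.head(5)[["term_id", "k", "n", "M", "N", "frequency", "p_value"]]
print("\ntop terms (k of n query genes hit a term annotating M of N genes):")
print(top.to_string(index=False))
hit = top.iloc[0]["term_id"] in truth.enriched_terms
print(f"\nthe top-ranked term is {'one of' if hit else 'NOT one of'} the planted "
      "enriched terms; small p-values flag terms over-represented beyond the "
      "hypergeometric expectation n*M/N.")
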