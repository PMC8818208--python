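"""Pairwise and groupwise similarity on a seven-term toy taxonomy.

Builds the small is_a hierarchy used throughout the test suite, estimates
corpus information content from four annotated patients, and prints the
main term-term and profile-profile similarity values.
"""

from phenosim import (
    AnnotationCorpus,
    OntologyGraph,
    PhenotypeProfile,
    corpus_ic,
    gw_gic,
    gw_indirect,
    gw_ui,
    sim_rada,
    sim_resnik_pw,
)

# root r; a,b under r; c,d under a; e under b; f under c
graph = OntologyGraph(
    {"r": set(), "a": {"r"}, "b": {"r"}, "c": {"a"}, "d": {"a"}, "e": {"b"}, "f": {"c"}}
)
corpus = AnnotationCorpus.from_dict(
    {"P1": {"f"}, "P2": {"d"}, "P3": {"e"}, "P4": {"c", "e"}}
)
ic = corpus_ic(graph, corpus)

print("corpus IC (annotation-frequency, nats):")
for term in sorted(graph.terms):
    print(f"  IC({term}) = {ic[term]:.4f}")

print(f"\nsim_rada(c, d)      = {sim_rada(graph, 'c', 'd'):.4f}   # path c-a-d, 1/(2+1)")
print(f"sim_rada(c, e)      = {sim_rada(graph, 'c', 'e'):.4f}   # path c-a-r-b-e")
print(f"sim_resnik(c, d)    = {sim_resnik_pw(graph, 'c', 'd', ic):.4f}   # IC of MICA a")

A = PhenotypeProfile("A", frozenset({"f"}))
B = PhenotypeProfile("B", frozenset({"d"}))
print(f"\ngroupwise, profiles A={{f}} vs B={{d}}:")
print(f"  ancestor-union overlap = {gw_ui(graph, A, B):.4f}")
print(f"  GIC (IC-weighted)      = {gw_gic(graph, A, B, ic):.4f}")
print(f"  best-match average / Resnik = {gw_indirect(graph, A, B, 'resnik', 'bma', ic):.4f}")
print("\nGIC downweights the shallow shared ancestors {a, r}, which carry")
print("little information relative to the specific unshared terms.")
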