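"""Compare corpus-frequency and structural information content.

Generates a seeded synthetic ontology with noisy admission profiles and
shows how the different IC measures score the ubiquitous noise terms
versus rare disease-specific terms.
"""

import numpy as np

from phenosim import SyntheticSpec, corpus_ic, generate_benchmark, structural_ic
from phenosim.synthetic import partition_terms

spec = SyntheticSpec(seed=0, n_admissions=300)
graph, diseases, admissions, corpus = generate_benchmark(spec)

noise_pool, _ = partition_terms(graph, spec)
freq: dict = {}
for adm in admissions:
    for t in adm.profile.terms:
        freq[t] = freq.get(t, 0) + 1
common_noise = sorted(set(noise_pool) & set(freq), key=lambda t: -freq[t])[:5]
rare_signal = sorted(
    (t for d in diseases.values() for t in d if t in freq), key=lambda t: freq[t]
)[:5]

tables = {
    "corpus": corpus_ic(graph, corpus),
    "seco": structural_ic(graph, "seco"),
    "zhou": structural_ic(graph, "zhou"),
    "sanchez": structural_ic(graph, "sanchez"),
}

print(f"{len(admissions)} admissions, {corpus.n_annotations} annotations\n")
print("mean IC of the 5 most frequent noise terms vs 5 rarest signal terms:")
for name, table in tables.items():
    noise_ic = np.mean([table[t] for t in common_noise])
    signal_ic = np.mean([table[t] for t in rare_signal])
    print(f"  {name:8s}  noise {noise_ic:6.3f}   signal {signal_ic:6.3f}")
print("\nCorpus IC separates the two groups by observed frequency; structural")
print("measures react only to where a term sits in the hierarchy, so they")
print("penalise ubiquitous terms only insofar as those terms are general.")
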