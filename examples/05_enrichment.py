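"""Fisher-exact gene-set enrichment of a query list against a GMT library.

Each term's P is the hypergeometric upper tail for the observed overlap;
P-values are BH-adjusted across the library and ranked by adjusted P,
then overlap size.  A term built to contain most of the query should
dominate the ranking.
"""

import numpy as np

from netmark.enrich import enrich_library, enrichment_frame
from netmark.io_formats import GeneSet, GeneSetLibrary

rng = np.random.default_rng(3)
universe = [f"G{i:04d}" for i in range(500)]
query = set(rng.choice(universe, size=25, replace=False))

lib = GeneSetLibrary()
planted = set(rng.choice(sorted(query), size=20, replace=False)) | set(
    rng.choice(universe, size=10, replace=False)
)
lib.sets["PLANTED_TERM"] = GeneSet("term built around the query", planted)
for i in range(10):
    members = set(rng.choice(universe, size=30, replace=False))
    lib.sets[f"RANDOM_{i}"] = GeneSet("random background term", members)

rows = enrich_library(query, lib, universe=set(universe), alpha=0.05)
print(enrichment_frame(rows).to_string(index=False))
# 'overlap' is k/K: query genes found in the term over the term's size;
# only terms with BH-adjusted P < 0.05 survive the filter.
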