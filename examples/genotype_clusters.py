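"""Genotype a breakpoint from spanning-pair insert sizes.

Fragments that cross an insertion lose the inserted bases from their
apparent insert size.  A homozygous site shows one shifted mode; a
heterozygous site adds the unshifted library mode.  DBSCAN (eps = 50 bp,
min_samples = 2) counts the modes.
"""

import numpy as np

from clipins.genotyper import GenotypeConfig, SpanningPair, call_genotype

rng = np.random.default_rng(1)
cfg = GenotypeConfig()
ins_len = 250

hom = rng.normal(500 - ins_len, 20, size=8)
het = np.concatenate([rng.normal(500, 20, 10), rng.normal(500 - ins_len, 20, 5)])

for label, sizes in [("homozygous site", hom), ("heterozygous site", het)]:
    pairs = [SpanningPair(0, 600, int(i)) for i in sizes]
    call = call_genotype(pairs, cfg)
    print(f"{label}: {call.n_clusters} cluster(s) -> {call.genotype}")
# One cluster of shifted insert sizes -> homozygous; shifted + library-mode
# clusters -> heterozygous.  Separation requires the insertion to be longer
# than the cluster radius relative to the insert-size spread.
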