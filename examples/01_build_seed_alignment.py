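"""Build a seed alignment from per-instance consensus alignments.

Constructs a toy family: a 60 bp consensus with several genomic copies,
two of which are post-insertion duplicates (identical flanking DNA), one
of which carries a 2 bp insertion. The pipeline removes the duplicated
copy, samples, and joins the rest into a multiple alignment in consensus
coordinates.
"""

import numpy as np

from repeatcal import (
    InstanceAlignment,
    dedupe_duplicated_copies,
    join_to_msa,
    sample_seed,
)

rng = np.random.default_rng(1)
consensus = "".join(rng.choice(list("ACGT"), size=60))
flank = "".join(rng.choice(list("ACGT"), size=250))
other_flank = "".join(rng.choice(list("ACGT"), size=250))

# three genomic copies: two sharing identical flanks (a segmental
# duplication of an existing insertion), one independent with a 2 bp insert
genome = {
    "chr1": flank + consensus + flank,
    "chr2": flank + consensus + flank,
    "chr3": other_flank + consensus[:20] + "GG" + consensus[20:] + other_flank,
}

instances = [
    InstanceAlignment("copy1", "chr1", 251, 310, "+", consensus, consensus,
                      divergence=0.02, consensus_coverage=1.0),
    InstanceAlignment("copy2", "chr2", 251, 310, "+", consensus, consensus,
                      divergence=0.05, consensus_coverage=1.0),
    InstanceAlignment("copy3", "chr3", 251, 312, "+",
                      consensus[:20] + "GG" + consensus[20:],
                      consensus[:20] + "--" + consensus[20:],
                      divergence=0.03, consensus_coverage=1.0),
]

deduped = dedupe_duplicated_copies(instances, genome)
print(f"{len(instances)} copies -> {len(deduped)} after duplicate-flank "
      f"removal (kept the lower-divergence duplicate)")

sampled = sample_seed(deduped, max_members=2000, rng_seed=42,
                      consensus=consensus)
msa = join_to_msa(sampled, consensus, family_id="TOYFAM")
print(f"seed alignment: {msa.n_members} members, "
      f"{len(msa.consensus)} match columns, width {len(msa.rf)}")
print("RF :", msa.rf)
for name, row in zip(msa.member_ids, msa.members):
    print(f"{name}: {row}")
# the lowercase 'gg' column pair is copy3's insertion; other rows carry
# '.' there because they have no residues opposite the consensus gap
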