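"""From simulated shotgun reads to an inferred fiber degradation profile.

Simulates a small community with two fiber-degrading enzymes planted at
70%/30% read proportions, re-profiles the reads with the built-in translated
matcher, and multiplies the enzyme counts by the interaction matrix. The
recovered EC proportions should match the planted ones up to binomial noise,
and each fiber's capacity is the sum of its contributing enzyme counts.
"""

import pandas as pd

from fiberdeg import ECProfile, compute_ifdp, load_default_catalogs, profile_reads
from fiberdeg.catalog import build_interaction_matrix
from fiberdeg.simulate import SimulationSpec, generate_community_reads, synthetic_reference

db = synthetic_reference(["3.2.1.4", "3.2.1.8"], length_aa=300, seed=0)
recs = list(db)
proteins = {r.accession: (next(iter(r.ecs)), r.sequence) for r in recs}
abundances = {recs[0].accession: 0.7, recs[1].accession: 0.3}

spec = SimulationSpec(proteins, abundances, n_reads=10_000, seed=1)
reads, truth = generate_community_reads(spec)
counts, report = profile_reads(reads, db)

print("planted proportions: 3.2.1.4=0.70, 3.2.1.8=0.30")
print("recovered counts:", {ec: int(c) for ec, c in counts.items()})
print(f"recovered proportion of 3.2.1.4: {counts['3.2.1.4'] / counts.sum():.3f}")
print(f"ambiguous-hit fraction: {report.ambiguity_fraction:.4f}")

fibers, enzymes = load_default_catalogs()
matrix = build_interaction_matrix(fibers, enzymes)
ffp = ECProfile(counts.rename("sample1").to_frame().T)
ifdp = compute_ifdp(ffp, matrix)
nonzero = ifdp.data.loc["sample1"]
print("\nfiber degradation capacities (nonzero):")
print(nonzero[nonzero > 0].to_string())
# cellulase (3.2.1.4) contributes to every beta-1,4-glucan-containing fiber,
# xylanase (3.2.1.8) to the xylan-backbone fibers.
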