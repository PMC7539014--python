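"""Design arithmetic for a cellular-barcoding experiment.

How many clones does a low-MOI transduction create, how many cells carry each
barcode after expansion and at injection, and how many cells does a PCR input
mass actually interrogate?
"""

from clonetrace import (
    cells_analyzed,
    cells_per_barcode,
    expected_transduced_clones,
    genome_equivalents,
)

clones = expected_transduced_clones(200_000, moi=0.1)
print(f"transduced clones at MOI 0.1           : {clones:,.0f}")
print(f"  (Poisson-corrected                   : "
      f"{expected_transduced_clones(200_000, 0.1, 'poisson'):,.1f})")
print(f"cells per barcode after expansion to 1e8: "
      f"{cells_per_barcode(100_000_000, 20_000):,.0f}")
print(f"cells per barcode in a 1e6-cell graft   : "
      f"{cells_per_barcode(1_000_000, 20_000):,.0f}")
genomes = genome_equivalents(80, genome_mass_pg=6.6, round_to=100)
print(f"genome equivalents in 80 ng mouse DNA   : {genomes:,.0f}")
print(f"cells analyzed across 8 PCR reactions   : "
      f"{cells_analyzed(8, genome_equivalents(80, 6.6), round_to=1000):,.0f}")

# At MOI 0.1 almost every transduced cell carries exactly one barcode, so
# the clone count is n_cells * MOI; 8 reactions of ~12,100 genomes mean each
# sample's barcode profile reflects roughly 97,000 cells.
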