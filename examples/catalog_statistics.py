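"""Summarize the packaged SK1 Ty catalog.

Loads the 30-element insertion catalog, prints family counts, tRNA
adjacency, target-site-duplication statistics, the genome fraction occupied
by full-length elements, and the target-site consensus.
"""
from tymap import build_analysis_regions, catalog_summary, load_sk1_catalog, tsd_consensus

catalog = load_sk1_catalog()
summary = catalog_summary(catalog)

print(f"elements:          {summary.n_total}")
print(f"family counts:     {summary.family_counts}")
print(f"tRNA-adjacent:     {summary.trna_adjacent_count} of "
      f"{summary.n_non_ty5} non-Ty5 elements "
      f"({100 * summary.trna_fraction:.0f}%)")
print(f"TSD determined:    {summary.tsd_determined} sites, "
      f"{summary.tsd_perfect} with a perfect 5-bp duplication "
      f"({100 * summary.tsd_perfect_fraction:.1f}%)")
print(f"genome fraction:   {summary.genome_fraction(6000, 12.1e6)}% "
      "(assuming 6-kb elements in a 12.1-Mb genome)")

regions = build_analysis_regions(catalog)
print(f"analysis regions:  {len(regions)} after merging neighbors and "
      "excluding the subtelomeric Ty5")

tsds = [e.tsd for e in catalog if e.has_tsd_sequence]
consensus = tsd_consensus(tsds)
print(f"TSD consensus:     {consensus.consensus} "
      f"(from {consensus.n_observations} duplications; IUPAC codes mark ties)")
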