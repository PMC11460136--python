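"""Screen diagnostic SNPs from the bundled synthetic Fritillaria alignments.

Builds eleven-species ITS and matK toy alignments, screens for columns that
separate the six-species target group (FCB) from the five adulterants and
for columns unique to each adulterant, and prints the assembled panel.
"""

from herbq import discover_panel, fritillaria_demo

grouping, alignments = fritillaria_demo(seed=0)
panel = discover_panel(alignments, grouping)

print(f"panel of {len(panel.sites)} sites (primary = {panel.primary.key}):\n")
for site in panel.sites:
    print(
        f"  {site.key:>9}  {site.mode:<18} {site.label:<16} "
        f"{site.target_allele}/{site.background_allele}  "
        f"flank {site.flank.marked[:40]}..."
    )
print("\ncoverage (species -> site):")
for taxon, key in sorted(panel.coverage.items()):
    print(f"  {taxon:<32} {key}")

# The group site carries one base in all six FCB species and another in all
# five adulterants, so any adulteration shows up as a second allele there;
# the per-species sites then type which adulterant is present.  The two FPB
# species share one joint site because no column separates them individually.
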