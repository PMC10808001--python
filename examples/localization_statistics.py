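"""Localization-stratified comparison of element properties.

Simulates a labelled homolog family in which mitochondrial/chloroplast
sequences carry K/R-enriched, hydrophobicity-lowered amphipathic elements
whose hydrophobic moment is matched to the other groups by construction,
then tests which properties separate the groups.
"""

from amphihelix import default_tables, detect_elements
from amphihelix.stats import compare_by_localization, element_property_frame
from amphihelix.synth import FamilySpec, synth_family

tables = default_tables()
records, labels, truth = synth_family(FamilySpec(), seed=42)
elements_by_id = {r.id: detect_elements(r, tables) for r in records}
frame = element_property_frame(records, elements_by_id, labels, tables)
report = compare_by_localization(frame)

print(f"{len(records)} sequences, {len(frame)} detected elements")
print("group sizes:", report["groups"], "\n")
for prop, block in report["properties"].items():
    omnibus = block["omnibus"]
    print(f"{prop:>15}: Kruskal-Wallis H = {omnibus['statistic']:7.2f}, "
          f"p = {omnibus['p_value']:.3g}")
    for pw in block["pairwise"]:
        if set(pw["groups"]) == {"mitochondrial", "other"}:
            print(f"{'':>17}mitochondrial vs other: CLES = {pw['cles']:.2f}, "
                  f"median diff = {pw['median_diff']:+.3f}, "
                  f"Holm p = {pw['adjusted_p']:.3g}")

print("\nBasic-residue fraction and mean hydrophobicity separate the groups")
print("(planted composition shift); the hydrophobic moment does not -- the")
print("generator holds it constant across groups, mirroring elements that")
print("adapt their composition to their target organelle while keeping the")
print("same amphipathic strength.")
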