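"""Annotate observed m/z values against the bundled compound library.

A measured mass alone rarely identifies a compound: isomers share a
formula and different adducts of different compounds can collide. The
matcher therefore returns every (compound, adduct) candidate within the
ppm tolerance and reports per-feature ambiguity.
"""

from mzpathway import ambiguity_report, bundled_adduct_rules, bundled_library, match_features

library = bundled_library()
rules = bundled_adduct_rules(ppm_tolerance=5.0)

# a measured feature from a stool metabolome, negative ion mode
observed = [431.3164, 145.0505, 83.0139]
matches = match_features(observed, library, rules, ion_mode="negative")

print("candidates (observed -> compound via adduct, ppm error):")
for c in matches.candidates:
    name = library.compounds[c.compound_id].name
    print(f"  {c.feature_mz:10.4f} -> {name:42s} {c.adduct_label:12s} "
          f"{c.ppm_error:+.2f} ppm")

print("\nambiguity per feature (>=2 candidate compounds = ambiguous):")
print(ambiguity_report(matches).to_string(index=False))
print("\n431.3164 matches two C27H44O4 isomers - mass alone cannot tell a")
print("bile-acid intermediate from a vitamin D3 derivative; both candidates")
print("are carried into pathway scoring.")
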