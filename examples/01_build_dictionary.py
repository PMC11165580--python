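"""Build the hierarchical enzyme dictionary and look inside it.

The dictionary is the heart of the annotator.  Every enzyme name from the
nomenclature list is expanded into its spelling variants (hyphen vs space
separators, Greek letters vs their spelled-out names) and filed into a
*branch* keyed by the name's final word — its root term, "dehydrogenase"
for "alcohol dehydrogenase".  Names that do not end in "-ase" (trypsin,
lysozyme, ...) live in a parallel set of branches.  Within a branch,
longer names sort first so that matching is greedy: "aliphatic alcohol
dehydrogenase" wins over the nested "alcohol dehydrogenase".

Run:  python examples/01_build_dictionary.py
"""

from enzner.dictionary import (
    build_hierarchy,
    expand_variants,
    default_greek_table,
    load_mini_dictionary,
)

entries = load_mini_dictionary()
print(f"loaded {len(entries)} nomenclature entries")
print("first entry:", entries[0].ec_number, entries[0].names)

# variant expansion: one hyphen choice x one alphabet choice
greek = default_greek_table()
print("\nvariants of 'beta-galactosidase':")
for v in sorted(expand_variants("beta-galactosidase", greek)):
    print("  ", v)

tree = build_hierarchy(entries, greek)
print(f"\nhierarchy: {len(tree)} surface forms, "
      f"{len(tree.branches)} '-ase' branches, "
      f"{len(tree.non_ase_branch)} other branches")

print("\nthe 'dehydrogenase' branch (longest first):")
for form in tree.branches["dehydrogenase"][:8]:
    ec = tree.ec_index.get(form, "?")
    print(f"  {ec:<12} {form}")

# branch keys are final whitespace tokens, so names ending in a
# parenthesized qualifier produce punctuation-laden keys; show the plain ones
plain = [k for k in sorted(tree.non_ase_branch) if k.isalpha() and len(k) > 3]
print("\nnon-'-ase' enzymes include:", plain[:6])
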