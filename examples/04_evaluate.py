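"""Score annotations with partial-positive credit and measure agreement.

A *partial positive* is a prediction that overlaps a gold entity but only
captures its root term ("kinase" for "Ser/Thr kinase") or drops a
trailing isoform marker ("carboxylesterase" for "carboxylesterase 2").
Partial positives earn half credit: pp/2 joins the true positives and
pp/2 the false negatives (and false positives, by default).  Agreement
between two annotators is a Jaccard index, exact at the entity level or
overlap-based at the character level.

Run:  python examples/04_evaluate.py
"""

from enzner.evaluation import (
    Span,
    agreement,
    classify_matches,
    f1_score,
    scores,
)

gold = [
    Span(0, 14, "Ser/Thr kinase"),
    Span(40, 18, "carboxylesterase 2"),
    Span(80, 8, "catalase"),
    Span(120, 7, "trypsin"),
]
pred = [
    Span(8, 6, "kinase"),             # partial: root term only
    Span(40, 16, "carboxylesterase"),  # partial: isoform marker missed
    Span(80, 8, "catalase"),          # exact
    Span(200, 8, "protease"),         # spurious
]

counts = classify_matches(pred, gold)
print(f"tp={counts.tp} fp={counts.fp} fn={counts.fn} pp={counts.pp}")

s = scores(counts)
print(f"precision={s.precision:.3f} recall={s.recall:.3f} f1={s.f1:.3f}")

# the half-credit arithmetic, spelled out
print("\neffective tp = tp + pp/2 =", counts.tp + counts.pp / 2)
print("f1 from a published-scale P/R pair:",
      round(f1_score(0.996, 0.762), 3))

# inter-annotator agreement between two near-identical annotation sets
other = gold[:3] + [Span(120, 15, "serum trypsinase")]
ent = agreement(gold, other, level="entity")
chars = agreement(gold, other, level="character")
print(f"\nentity-level Jaccard:    {ent.jaccard:.3f} "
      f"(agreed={ent.agreed}, a_only={ent.a_only}, b_only={ent.b_only})")
print(f"character-level Jaccard: {chars.jaccard:.3f}")
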