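"""The label aggregation rule, worked through by hand.

A fine-tuned classifier scores each tokenization of a segment with three
probabilities (bacteria, phage, paradox). "Paradox" means "the attached
label token is wrong", so its mass is evidence for the *other* class:
with [PHA] attached it counts toward bacteria, with [BAC] attached
toward phage. The two aggregated phage scores per segment are averaged,
and a contig is called a phage iff its mean phage score exceeds 0.5.
"""

from condphage import ClassScores, aggregate_scores
from condphage.predict import call_from_score
from condphage.tokenizer import BAC, PHA

examples = [
    ClassScores(BAC, 0.70, 0.10, 0.20),  # [BAC] attached, mostly 'bacteria'
    ClassScores(PHA, 0.10, 0.15, 0.75),  # [PHA] attached, mostly 'paradox'
    ClassScores(BAC, 0.05, 0.15, 0.80),  # [BAC] attached, mostly 'paradox'
    ClassScores(PHA, 0.05, 0.85, 0.10),  # [PHA] attached, mostly 'phage'
]

for s in examples:
    out = aggregate_scores(s)
    print(f"{s.attached_label} (bac={s.p_bac:.2f}, pha={s.p_pha:.2f}, par={s.p_par:.2f})"
          f" -> binary (bac={out.b_bac:.2f}, pha={out.b_pha:.2f})")

# one two-segment contig: segments 1+2 and 3+4 above
seg1 = (aggregate_scores(examples[0]).b_pha + aggregate_scores(examples[1]).b_pha) / 2
seg2 = (aggregate_scores(examples[2]).b_pha + aggregate_scores(examples[3]).b_pha) / 2
contig = (seg1 + seg2) / 2
print(f"\nsegment phage scores: {seg1:.3f}, {seg2:.3f}")
print(f"contig phage score {contig:.3f} -> call: {call_from_score(contig)}")
print("Note the first segment reads 'bacteria' both ways; the second reads")
print("'phage' both ways (paradox under [BAC] is evidence for phage).")
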