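"""Clean free-text emotion labels and compute vocabulary metrics.

Shows the label-cleaning pipeline (case, punctuation, stopwords,
derivational lemmatization), the per-clip unique-label count (NUL), and
norms-based lexical complexity (age of acquisition, familiarity).
"""

from emoseg import clean_labels, lexical_complexity
from emoseg.synthetic import build_norms

raw = ["Angry!", "he looks angry", "anger", "2 very sad :(", "worried", "EXASPERATION"]
cleaned = clean_labels(raw)
print(f"raw labels: {raw}")
print(f"cleaned lemmas: {cleaned.lemmas}")
print(f"dropped tokens: {cleaned.dropped}")
print(f"unique labels: {sorted(cleaned.unique)}  (NUL contribution = {len(cleaned.unique)})")

norms = build_norms()
aoa, familiarity, coverage = lexical_complexity(cleaned.lemmas, norms)
print(f"\nmean age of acquisition: {aoa:.2f} years")
print(f"mean familiarity: {familiarity:.2f} (1-7 rating)")
print(f"norms coverage: {coverage:.2f}")
print(
    "\nangry/anger collapse to one lemma, so richer inflection does not inflate"
    "\nthe unique-label count; later-acquired words (exasperation) raise mean AoA."
)
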