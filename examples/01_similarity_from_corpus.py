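"""Build symptom-disease similarities from a small co-mention corpus.

Each record is a set of symptom terms and disease terms that appeared in the
same bibliographic entry.  Cosine similarity between co-occurrence profiles
quantifies how specifically a symptom accompanies a disease in the
literature.
"""

from symgene import RecordCorpus, build_similarity_table

records = [
    ("r1", {"headache", "nausea"}, {"migraine"}),
    ("r2", {"headache"}, {"migraine"}),
    ("r3", {"headache", "photophobia"}, {"migraine"}),
    ("r4", {"fever", "cough"}, {"influenza"}),
    ("r5", {"fever", "headache"}, {"influenza"}),
    ("r6", {"cough"}, {"influenza", "bronchitis"}),
    ("r7", {"cough", "fever"}, {"bronchitis"}),
]
corpus = RecordCorpus.from_records(records)
table = build_similarity_table(corpus)

print(table.to_frame().to_string(index=False))
print()
print(
    "Each row scores one symptom-disease pair in [0, 1]; e.g. headache is far\n"
    "more similar to migraine than to bronchitis because their co-occurrence\n"
    "profiles over the symptom vocabulary point in nearly the same direction."
)
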