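"""Generate a clustered synthetic literature and inspect its structure.

The generator emulates what the retrieval method exploits in a real corpus
of papers: topical clusters with their own vocabulary, citation pools
shared within a cluster, and graded relevance of each document to its
cluster's query topic.
"""

from bibrank import generate
from bibrank.synthetic import GeneratorConfig

corpus, topics, qrels = generate(GeneratorConfig(seed=7))

print(f"documents: {len(corpus)}, topics: {len(topics)}, judgments: {len(qrels)}")

doc = corpus[0]
print(f"\nfirst document {doc.doc_id!r}:")
print(f"  title:      {doc.title}")
print(f"  abstract:   {doc.abstract[:70]}...")
print(f"  paragraphs: {len(doc.paragraphs)}")
print(f"  references: {doc.references[:4]} ...")

topic = topics[0]
print(f"\ntopic {topic.topic_id}: question = {topic.question!r}")
grades = qrels.judged_docs(topic.topic_id)
from collections import Counter

print(f"grade counts for topic 1: {dict(Counter(grades.values()))}")
print("(grade 2 = core papers of the cluster, 1 = peripheral, 0 = other clusters)")
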