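"""Fine-tune the embedder on the retrieval system's own output.

The full hybrid system judges documents with more evidence than the bare
embedder (keywords + paragraphs), so its ranked lists can teach the
embedder: top-3 documents per topic become positives, the bottom 15
negatives, paired five-per-positive — 15 triplets per topic, with no
labels involved at any point.
"""

from bibrank import (
    BagOfWordsEmbedder,
    FusionConfig,
    MinerConfig,
    TrainConfig,
    build_citation_matrix,
    build_index,
    build_neural_index,
    build_teacher_set,
    embed_bibliographies,
    evaluate_run,
    mine_triplets,
    search,
    train,
)
from bibrank.synthetic import GeneratorConfig, cluster_vocabulary, generate

config = GeneratorConfig(seed=11)
corpus, topics, qrels = generate(config)
cmatrix = build_citation_matrix(corpus)
space = embed_bibliographies(cmatrix, k=min(cmatrix.shape) // 4)

embedder = BagOfWordsEmbedder(cluster_vocabulary(config), dim=32, seed=11)
train(embedder, mine_triplets(corpus, space, MinerConfig(seed=11)),
      TrainConfig(epochs=3, learning_rate=0.05, seed=11))

bm25 = build_index(corpus)


def full_system_run():
    nindex = build_neural_index(corpus, embedder)
    return [search(t.query_text(), embedder, nindex, bm25, corpus,
                   FusionConfig(), topic_id=t.topic_id) for t in topics]


lists = full_system_run()
before = evaluate_run(lists, qrels).means
print("mean metrics before teacher step:",
      {k: round(v, 3) for k, v in before.items()})

teacher = build_teacher_set(lists, corpus)
print(f"teacher set: {len(teacher)} triplets "
      f"({len(topics)} topics x 15)")
train(embedder, teacher, TrainConfig(epochs=2, learning_rate=0.05, seed=11))

after = evaluate_run(full_system_run(), qrels).means
print("mean metrics after teacher step: ",
      {k: round(v, 3) for k, v in after.items()})
print("\nthe teacher loop distills the full system's judgment back into "
      "the embedder without using any relevance labels")
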