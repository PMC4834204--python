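"""Self-contained synthetic-recovery experiments.

Train on one seeded synthetic corpus and evaluate on an independently seeded
corpus from the same grammar: if the pipeline is mechanically correct it must
recover the planted mentions almost perfectly, because the generator's signal
(morpheme grammar + matched lexicons + planted embedding/cluster structure)
is fully available to the feature extractor.  These runs back both the test
suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import brown as brown_mod
from . import features as F
from . import pipeline, synthetic, tagger
from .embeddings import binarize
from .evaluate import CempReport, CpdReport, evaluate_cemp, evaluate_cpd
from .postprocess import StructureWordLexicon
from .preprocess import split_sentences, tokenize


@dataclass
class ExperimentResult:
    cemp: CempReport
    cpd: CpdReport
    n_train_docs: int
    n_test_docs: int
    n_train_entities: int
    n_test_entities: int


def lowercased_sentences(documents) -> list[list[str]]:
    """Whitespace/punctuation-tokenized, lowercased sentences of a corpus."""
    out: list[list[str]] = []
    for doc in documents:
        for section in ("T", "A"):
            text = doc.section_text(section)
            for span in split_sentences(text):
                toks = [t.surface.lower() for t in tokenize(text, span)]
                if toks:
                    out.append(toks)
    return out


def run_recovery_experiment(
    train_seed: int,
    test_seed: int,
    n_train_docs: int = 100,
    n_test_docs: int = 50,
    char_noise_rate: float = 0.0,
    use_brown: bool = True,
    use_embedding: bool = True,
    brown_clusters: int = 16,
    embedding_dim: int = 10,
    epochs: int = 8,
    apply_postprocess: bool = True,
) -> ExperimentResult:
    """Simulate -> train -> tag -> post-process -> evaluate, two seeds apart.

    Word-representation resources (Brown paths, binarized embeddings) are
    built from the union of both corpora's *unlabeled* text, mirroring how
    such features are learned from large unannotated collections that may
    include the evaluation documents.
    """
    train_corpus = synthetic.generate_corpus(
        synthetic.GrammarConfig(
            n_documents=n_train_docs, char_noise_rate=char_noise_rate, seed=train_seed
        )
    )
    test_corpus = synthetic.generate_corpus(
        synthetic.GrammarConfig(
            n_documents=n_test_docs, char_noise_rate=char_noise_rate, seed=test_seed
        )
    )

    cluster_paths = None
    if use_brown:
        sentences = lowercased_sentences(
            train_corpus.documents
        ) + lowercased_sentences(test_corpus.documents)
        cluster_paths = brown_mod.cluster(sentences, brown_clusters, min_count=2)

    binarized = None
    if use_embedding:
        vocab = synthetic.corpus_token_vocab(
            train_corpus.documents
        ) | synthetic.corpus_token_vocab(test_corpus.documents)
        chems = synthetic.chemical_token_vocab(
            train_corpus
        ) | synthetic.chemical_token_vocab(test_corpus)
        binarized = binarize(
            synthetic.generate_embeddings(sorted(vocab), chems, embedding_dim, train_seed)
        )

    resources = F.Resources(
        affix_lexicon=F.AffixLexicon(train_corpus.affix_lexicon),
        gene_lexicon=F.GeneLexicon(train_corpus.gene_lexicon),
        cluster_paths=cluster_paths,
        binarized=binarized,
    )
    feat_cfg = F.FeatureConfig(use_brown=use_brown, use_embedding=use_embedding)
    data = pipeline.training_sequences(
        train_corpus.documents, train_corpus.annotations, resources, feat_cfg
    )
    model = tagger.train(data, tagger.TrainConfig(epochs=epochs, seed=train_seed))
    out = pipeline.run(
        test_corpus.documents,
        model,
        resources,
        feat_cfg,
        StructureWordLexicon(test_corpus.structure_lexicon),
        apply_postprocess=apply_postprocess,
    )
    cemp = evaluate_cemp(test_corpus.annotations, out.predictions)
    gold_sections = {(a.doc_id, a.section) for a in test_corpus.annotations}
    cpd = evaluate_cpd(gold_sections, out.section_predictions)
    return ExperimentResult(
        cemp=cemp,
        cpd=cpd,
        n_train_docs=n_train_docs,
        n_test_docs=n_test_docs,
        n_train_entities=len(train_corpus.annotations),
        n_test_entities=len(test_corpus.annotations),
    )
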