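"""Brown clustering: hierarchical word classes from class-bigram statistics.

Words are grouped by the similarity of their left/right neighbor
distributions.  The objective is the average mutual information (AMI) of the
class bigram model,

    AMI = sum over class pairs (c, c') of
          p(c, c') * log2( p(c, c') / (p_left(c) * p_right(c')) ),

where p(c, c') is the probability that an adjacent word bigram has its left
word in class c and its right word in class c'.  Clustering is greedy and
agglomerative: the most frequent C words start as singleton classes, the
remaining words are inserted most-frequent-first, and after each insertion
the pair of classes whose merge loses the least AMI is merged.  Finally the
C surviving classes are merged down to a single root; the record of merges
is a binary tree and every word's representation is its root-to-leaf path
written as a bit string (0 = earlier-created branch), e.g. ``110110110110``.

The implementation favors exactness over speed: every candidate merge is
scored by recomputing the AMI of the merged class-bigram table.  Intended
corpus scale is desk scale (up to roughly a million tokens, a few thousand
word types).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_TIE_EPS = 1e-12


@dataclass
class ClusterPaths:
    """Word -> (bit-string path, corpus count); leaf paths are prefix-free."""

    entries: dict[str, tuple[str, int]]

    def path(self, word: str) -> str | None:
        entry = self.entries.get(word)
        return None if entry is None else entry[0]


def count_bigrams(
    sentences: Sequence[Sequence[str]],
) -> tuple[Counter, Counter]:
    """Unigram and within-sentence adjacent-bigram counts, left-to-right."""
    if not sentences or all(len(s) == 0 for s in sentences):
        raise ValueError("empty corpus")
    unigrams: Counter = Counter()
    bigrams: Counter = Counter()
    for sent in sentences:
        unigrams.update(sent)
        bigrams.update(zip(sent, sent[1:]))
    return unigrams, bigrams


def ami_from_matrix(counts: np.ndarray) -> float:
    """AMI (log base 2) of a class-bigram count table."""
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts / total
    pl = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, p * np.log2(np.where(mask, p / (pl * pr), 1.0)), 0.0)
    return float(terms.sum())


def average_mutual_information(
    assignment: dict[str, int], bigrams: Counter
) -> float:
    """AMI of an explicit word->cluster assignment over word-bigram counts."""
    ids = sorted(set(assignment.values()))
    index = {cid: k for k, cid in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    for (left, right), count in bigrams.items():
        mat[index[assignment[left]], index[assignment[right]]] += count
    return ami_from_matrix(mat)


def _merged_matrix(counts: np.ndarray, i: int, j: int) -> np.ndarray:
    """Merge matrix rows/cols i and j (into position i, dropping j)."""
    out = counts.copy()
    out[i, :] += out[j, :]
    out[:, i] += out[:, j]
    out = np.delete(np.delete(out, j, axis=0), j, axis=1)
    return out


@dataclass
class _Node:
    node_id: int
    word: str | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None


def cluster(
    sentences: Sequence[Sequence[str]],
    n_clusters: int,
    min_count: int = 1,
    on_merge=None,
) -> ClusterPaths:
    """Greedy Brown clustering; returns each word's bit-string path.

    Ties between candidate merges (equal AMI loss within 1e-12) are broken by
    the lexicographically smallest pair of cluster creation ids, which makes
    the output deterministic for a given corpus and C.
    """
    unigrams, bigrams = count_bigrams(sentences)
    vocab = [w for w, c in unigrams.items() if c >= min_count]
    # frequency-sorted, ties alphabetical: fixes both init and insertion order
    vocab.sort(key=lambda w: (-unigrams[w], w))
    if not vocab:
        raise ValueError("no words above min_count")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > len(vocab):
        warnings.warn(
            f"n_clusters {n_clusters} exceeds vocabulary size {len(vocab)}; reduced",
            UserWarning,
            stacklevel=2,
        )
        n_clusters = len(vocab)

    kept = set(vocab)
    word_bigrams = Counter(
        {pair: c for pair, c in bigrams.items() if pair[0] in kept and pair[1] in kept}
    )

    next_id = 0

    def new_node(**kwargs) -> _Node:
        nonlocal next_id
        node = _Node(node_id=next_id, **kwargs)
        next_id += 1
        return node

    # active clusters: parallel lists of tree node and member-word set
    nodes: list[_Node] = []
    members: list[set[str]] = []
    counts = np.zeros((0, 0))

    def add_singleton(word: str) -> None:
        nonlocal counts
        k = len(nodes)
        nodes.append(new_node(word=word))
        members.append({word})
        grown = np.zeros((k + 1, k + 1))
        grown[:k, :k] = counts
        counts = grown
        for other_k, other_words in enumerate(members):
            for ow in other_words:
                counts[k, other_k] += word_bigrams.get((word, ow), 0)
                if other_k != k:
                    counts[other_k, k] += word_bigrams.get((ow, word), 0)

    def best_merge() -> tuple[int, int]:
        base = ami_from_matrix(counts)
        best_loss = np.inf
        best_pair: tuple[int, int] | None = None
        order = sorted(
            range(len(nodes)), key=lambda k: nodes[k].node_id
        )
        for a_pos in range(len(order)):
            for b_pos in range(a_pos + 1, len(order)):
                i, j = order[a_pos], order[b_pos]
                lo, hi = min(i, j), max(i, j)
                loss = base - ami_from_matrix(_merged_matrix(counts, lo, hi))
                if loss < best_loss - _TIE_EPS:
                    best_loss = loss
                    best_pair = (i, j)
        assert best_pair is not None
        return best_pair

    def merge(i: int, j: int) -> None:
        nonlocal counts
        if on_merge is not None:
            # snapshot of active clusters and the chosen pair, for auditing
            on_merge([frozenset(m) for m in members], (i, j))
        # earlier-created cluster becomes the 0 branch
        a, b = (i, j) if nodes[i].node_id < nodes[j].node_id else (j, i)
        parent = new_node(left=nodes[a], right=nodes[b])
        lo, hi = min(i, j), max(i, j)
        counts = _merged_matrix(counts, lo, hi)
        nodes[lo] = parent
        members[lo] = members[i] | members[j]
        del nodes[hi], members[hi]

    for word in vocab[:n_clusters]:
        add_singleton(word)
    for word in vocab[n_clusters:]:
        add_singleton(word)
        merge(*best_merge())
    while len(nodes) > 1:
        merge(*best_merge())

    paths: dict[str, tuple[str, int]] = {}

    def walk(node: _Node, prefix: str) -> None:
        if node.word is not None:
            paths[node.word] = (prefix, unigrams[node.word])
            return
        assert node.left is not None and node.right is not None
        walk(node.left, prefix + "0")
        walk(node.right, prefix + "1")

    walk(nodes[0], "")
    return ClusterPaths(paths)


def write_paths(paths: ClusterPaths, path: str | Path) -> None:
    """One line per word: ``bitstring<TAB>word<TAB>count``."""
    with open(path, "w", encoding="utf-8") as handle:
        for word in sorted(paths.entries, key=lambda w: (paths.entries[w][0], w)):
            bits, count = paths.entries[word]
            handle.write(f"{bits}\t{word}\t{count}\n")


def read_paths(path: str | Path) -> ClusterPaths:
    entries: dict[str, tuple[str, int]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 or set(fields[0]) - {"0", "1"}:
                raise ValueError(f"{path}:{lineno}: malformed cluster-path line")
            entries[fields[1]] = (fields[0], int(fields[2]))
    return ClusterPaths(entries)
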