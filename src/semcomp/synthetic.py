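"""Synthetic inputs: an LDA text corpus and random legal chess games.

Both generators stand in for external corpora so every analysis runs
without downloads.  The LDA corpus has controlled topical statistics
(sparse Dirichlets on both the document-topic and topic-word simplices,
concentration 0.1 by default) so that documents are dominated by a few
topics — separable but not perfectly.  The chess generator plays uniformly
random legal moves from the standard start, so emitted positions lie on
the legal-game manifold, giving the structured counterpart to their
occupancy-preserving shuffles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import chessrules as cr

__all__ = [
    "LdaParams",
    "GameRecord",
    "generate_lda_corpus",
    "generate_legal_games",
    "corpus_to_documents",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_vocab",
    "read_vocab",
    "games_to_pgn",
    "games_from_pgn",
]


@dataclass(frozen=True)
class LdaParams:
    """Generative settings for the synthetic topic-model corpus.

    Defaults are the study conditions: 1000-word vocabulary, 10 topics,
    concentration 0.1 on both Dirichlets, 20000 documents of 40 tokens.
    """

    vocab_size: int = 1000
    n_topics: int = 10
    doc_topic_concentration: float = 0.1
    topic_word_concentration: float = 0.1
    n_docs: int = 20000
    doc_length: int = 40
    seed: int = 0

    def __post_init__(self):
        if min(self.vocab_size, self.n_topics, self.n_docs, self.doc_length) < 1:
            raise ValueError("sizes must be positive")
        if min(self.doc_topic_concentration, self.topic_word_concentration) <= 0:
            raise ValueError("concentrations must be positive")


def generate_lda_corpus(params: LdaParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a bag-of-words corpus from a Latent Dirichlet Allocation model.

    Topic-word distributions phi_k ~ Dir(topic_word_concentration) are drawn
    once; each document draws theta ~ Dir(doc_topic_concentration) and its
    tokens iid from the mixture sum_k theta_k phi_k.

    Returns (counts, topics, doc_topics): an (n_docs, V) integer count
    matrix, the (K, V) topic-word matrix and the (n_docs, K) document-topic
    matrix — ground truth is returned to enable parameter-recovery tests.
    """
    rng = np.random.default_rng(params.seed)
    K, V = params.n_topics, params.vocab_size
    topics = rng.dirichlet([params.topic_word_concentration] * V, size=K)
    doc_topics = rng.dirichlet([params.doc_topic_concentration] * K, size=params.n_docs)
    word_p = doc_topics @ topics  # (n_docs, V) per-token word distribution
    word_p /= word_p.sum(axis=1, keepdims=True)
    counts = np.empty((params.n_docs, V), dtype=np.int64)
    for i in range(params.n_docs):
        counts[i] = rng.multinomial(params.doc_length, word_p[i])
    return counts, topics, doc_topics


@dataclass(frozen=True)
class GameRecord:
    """One synthetic game: the board after every ply, plus the move list."""

    boards: tuple  # tuple of length-64 int tuples, starting position first
    moves: tuple   # tuple of chessrules.Move

    @property
    def move_count(self) -> int:
        return len(self.moves)


def generate_legal_games(n_games: int, max_plies: int = 80, seed: int = 0
                         ) -> list[GameRecord]:
    """Play uniformly random legal moves from the standard starting position.

    Each game runs until checkmate, stalemate, insufficient material or
    ``max_plies`` plies.  Every intermediate position is legal by
    construction; the full state sequence (including the start) is recorded.
    """
    if n_games < 1:
        raise ValueError("n_games must be >= 1")
    rng = np.random.default_rng(seed)
    games = []
    for _ in range(n_games):
        pos = cr.Position()
        boards = [tuple(pos.board)]
        moves = []
        for _ply in range(max_plies):
            legal = pos.legal_moves()
            if not legal or pos.insufficient_material():
                break
            mv = legal[rng.integers(len(legal))]
            pos = pos.make(mv)
            moves.append(mv)
            boards.append(tuple(pos.board))
        games.append(GameRecord(boards=tuple(boards), moves=tuple(moves)))
    return games


def corpus_to_documents(corpus: np.ndarray | Sequence[Sequence[int]],
                        vocab: Sequence[str]) -> list[list[str]]:
    """Expand count vectors to token lists (inverse of bag-of-words counting).

    Tokens come out in vocabulary order; the round trip through
    ``bow_vectorize`` is the identity on counts.
    """
    counts = np.asarray(corpus)
    if counts.ndim == 1:
        counts = counts[None, :]
    if counts.shape[1] > len(vocab):
        raise ValueError("count vector longer than vocabulary")
    docs = []
    for row in counts:
        doc: list[str] = []
        for j in np.nonzero(row)[0]:
            doc.extend([vocab[j]] * int(row[j]))
        docs.append(doc)
    return docs


# --- plain-text IO --------------------------------------------------------


def write_corpus_jsonl(docs: Iterable[Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for doc in docs:
            fh.write(json.dumps(list(doc)) + "\n")


def read_corpus_jsonl(path) -> list[list[str]]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_vocab(words: Sequence[str], path, counts: Sequence[int] | None = None) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(words):
            fh.write(f"{w}\t{counts[i]}\n" if counts is not None else f"{w}\n")


def read_vocab(path) -> tuple[list[str], list[int] | None]:
    words, counts = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            words.append(parts[0])
            if len(parts) > 1:
                counts.append(int(parts[1]))
    return words, (counts if len(counts) == len(words) else None)


def games_to_pgn(games: Sequence[GameRecord], path) -> None:
    with open(path, "w") as fh:
        for g in games:
            fh.write(cr.moves_to_pgn(g.moves) + "\n")


def games_from_pgn(path) -> list[GameRecord]:
    with open(path) as fh:
        move_lists = cr.parse_pgn(fh.read())
    games = []
    for moves in move_lists:
        pos = cr.Position()
        boards = [tuple(pos.board)]
        for mv in moves:
            pos = pos.make(mv)
            boards.append(tuple(pos.board))
        games.append(GameRecord(boards=tuple(boards), moves=tuple(moves)))
    return games
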