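"""The DRM false-memory experiment: bag-of-words model, lists, recall.

Documents are order-free count vectors over a fixed vocabulary.  The text
autoencoder generates words independently through a linear transformation
of the decoder's last hidden activations followed by a softmax,

    e_i = exp(-z^T R x_i + b_{x_i}),    p(x_i | z) = e_i / sum_j e_j,

where the columns of R act as a semantic word embedding.  A studied DRM
list is encoded as a document; recall is simulated by sampling the
posterior and generating a list of distinct words, so that a non-studied
"lure" word that is semantically central to the list can intrude into the
reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bvae import BetaVAE, MultinomialLikelihood, TrainConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "DrmList",
    "WordGenParams",
    "bow_vectorize",
    "word_probabilities",
    "build_text_vae",
    "text_train_config",
    "word_gen_params",
    "reconstruct_word_list",
    "recall_frequencies",
    "filter_drm_lists",
    "nearest_associates",
    "build_synthetic_drm_lists",
    "random_word_list",
    "read_word_list",
    "write_word_list",
]


@dataclass(frozen=True)
class Vocabulary:
    """Ordered unique words with corpus occurrence counts."""

    words: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.words)) != len(self.words):
            raise ValueError("vocabulary words must be unique")
        if len(self.counts) != len(self.words):
            raise ValueError("one count per word required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "words", tuple(self.words))
        object.__setattr__(self, "counts", tuple(self.counts))

    @classmethod
    def from_corpus(cls, counts: np.ndarray, words: list[str] | None = None
                    ) -> "Vocabulary":
        """Vocabulary for a count-matrix corpus; synthesises w0000-style words."""
        totals = np.asarray(counts).sum(axis=0)
        if words is None:
            width = len(str(len(totals) - 1))
            words = [f"w{i:0{width}d}" for i in range(len(totals))]
        return cls(words=tuple(words), counts=tuple(int(c) for c in totals))

    def __len__(self) -> int:
        return len(self.words)

    def index(self, word: str) -> int:
        try:
            return self.words.index(word)
        except ValueError:
            raise KeyError(f"word {word!r} not in vocabulary") from None

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def count(self, word: str) -> int:
        return self.counts[self.index(word)]


@dataclass(frozen=True)
class DrmList:
    """A lure word plus the studied associates (the lure is never studied)."""

    lure: str
    studied: tuple[str, ...]

    def __post_init__(self):
        if self.lure in self.studied:
            raise ValueError("lure must not appear among studied words")
        if len(set(self.studied)) != len(self.studied):
            raise ValueError("studied words must be unique")
        object.__setattr__(self, "studied", tuple(self.studied))


@dataclass(frozen=True)
class WordGenParams:
    """Word-generation layer: semantic embedding R (|z| x |V|) and bias b."""

    R: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if R.ndim != 2 or b.shape != (R.shape[1],):
            raise ValueError("R must be |z| x |V| with b of length |V|")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "b", b)


def bow_vectorize(tokens, vocab: Vocabulary) -> np.ndarray:
    """Count tokens into a vocabulary-length vector; OOV tokens are dropped."""
    counts = np.zeros(len(vocab), dtype=np.int64)
    dropped = 0
    for tok in tokens:
        if tok in vocab:
            counts[vocab.words.index(tok)] += 1
        else:
            dropped += 1
    if dropped:
        logger.info("bow_vectorize dropped %d out-of-vocabulary tokens", dropped)
    return counts


def word_probabilities(z: np.ndarray, params: WordGenParams) -> np.ndarray:
    """softmax(-z^T R + b): the per-token word distribution given code z."""
    z = np.asarray(z, dtype=float)
    if z.shape != (params.R.shape[0],):
        raise ValueError(
            f"z has dimension {z.shape}, expected ({params.R.shape[0]},)"
        )
    logits = -z @ params.R + params.b
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def text_train_config(
    beta: float = 0.5,
    seed: int = 0,
    preset: str = "desk",
    n_steps: int | None = None,
) -> TrainConfig:
    """Training configuration for the text autoencoder.

    ``'full'`` is the reference architecture (two 2000-unit layers, 100
    latents, Adam at 1e-5, batch 100); ``'desk'`` is the small-corpus preset
    (one 256-unit layer, 32 latents, larger learning rate).  β defaults to
    0.5, the immediate-recall calibration for the synthetic corpus.
    """
    if preset == "full":
        return TrainConfig(
            beta=beta, learning_rate=1e-5, batch_size=100,
            n_steps=50000 if n_steps is None else n_steps,
            seed=seed, latent_dim=100, hidden_widths=(2000, 2000),
        )
    if preset == "desk":
        return TrainConfig(
            beta=beta, learning_rate=1e-3, batch_size=100,
            n_steps=2000 if n_steps is None else n_steps,
            seed=seed, latent_dim=32, hidden_widths=(256,),
        )
    raise ValueError(f"unknown preset {preset!r}")


def build_text_vae(config: TrainConfig, vocab: Vocabulary) -> BetaVAE:
    """β-VAE over bags of words with the independent word-generation decoder."""
    return BetaVAE(
        input_dim=len(vocab),
        likelihood=MultinomialLikelihood(len(vocab)),
        config=config,
    )


def word_gen_params(model: BetaVAE) -> WordGenParams:
    """Extract the word-generation layer (R, b) from a trained text model.

    The decoder's final linear layer computes logits = h W + c on the last
    hidden activations h; identifying with -h^T R + b gives R = -W, b = c.
    """
    final = model.decoder.layers[-1]
    return WordGenParams(R=-final.W.astype(float), b=final.b.astype(float))


def _distinct_sample(p: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """Sequential without-replacement draws with renormalisation."""
    p = p.astype(np.float64).copy()
    out: list[int] = []
    for _ in range(k):
        cum = np.cumsum(p)
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        idx = min(idx, len(p) - 1)
        out.append(idx)
        p[idx] = 0.0
    return out


def reconstruct_word_list(drm: DrmList, model: BetaVAE, vocab: Vocabulary,
                          n_samples: int = 100,
                          rng: np.random.Generator | None = None
                          ) -> list[list[str]]:
    """Sampled recall of a studied list, constrained to distinct words.

    Each sample encodes the studied words as a document, draws
    z ~ q(z|bow(studied)), and generates len(studied) distinct words by
    sequential sampling without replacement from the decoder's word
    distribution.
    """
    if not model.trained:
        from .bvae import NotTrainedError

        raise NotTrainedError("text model has not been trained")
    if len(drm.studied) > len(vocab):
        raise ValueError("list longer than the vocabulary")
    rng = np.random.default_rng(0) if rng is None else rng
    x = bow_vectorize(drm.studied, vocab).astype(np.float32)[None, :]
    mu, logvar, _ = model._encode_raw(x)
    std = np.exp(0.5 * logvar)
    out = []
    for _ in range(n_samples):
        z = mu + std * rng.standard_normal(size=mu.shape).astype(np.float32)
        logits = model.decode_logits(z)[0].astype(np.float64)
        logits -= logits.max()
        p = np.exp(logits)
        idx = _distinct_sample(p, len(drm.studied), rng)
        out.append([vocab.words[i] for i in idx])
    return out


def recall_frequencies(samples: list[list[str]], drm: DrmList) -> dict[str, float]:
    """Fraction of sampled lists containing each studied word and the lure."""
    if not samples:
        raise ValueError("samples must be non-empty")
    n = len(samples)
    sets = [set(s) for s in samples]
    freqs = {w: sum(w in s for s in sets) / n for w in drm.studied}
    freqs[drm.lure] = sum(drm.lure in s for s in sets) / n
    return freqs


def filter_drm_lists(lists, vocab: Vocabulary,
                     min_lure_count: int = 2000,
                     min_word_count: int = 100,
                     min_length: int = 12) -> list[DrmList]:
    """Corpus-frequency filtering of user-supplied DRM lists.

    Lists whose lure occurs fewer than ``min_lure_count`` times are dropped;
    studied words rarer than ``min_word_count`` are deleted; lists left
    shorter than ``min_length`` are dropped.
    """
    out = []
    for drm in lists:
        if drm.lure not in vocab or vocab.count(drm.lure) < min_lure_count:
            continue
        kept = tuple(
            w for w in drm.studied if w in vocab and vocab.count(w) >= min_word_count
        )
        if len(kept) < min_length:
            continue
        out.append(DrmList(lure=drm.lure, studied=kept))
    return out


def nearest_associates(params: WordGenParams, word: str, vocab: Vocabulary,
                       k: int = 15) -> list[str]:
    """k nearest vocabulary words by cosine similarity of embedding columns.

    The query itself is excluded; ties break by vocabulary index.
    """
    if k >= len(vocab):
        raise ValueError("k must be smaller than the vocabulary")
    qi = vocab.index(word)
    cols = params.R
    norms = np.linalg.norm(cols, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    sims = (cols.T @ cols[:, qi]) / (norms * norms[qi])
    sims[qi] = -np.inf
    # stable sort on -sims keeps lower indices first among ties
    order = np.argsort(-sims, kind="stable")
    return [vocab.words[i] for i in order[:k]]


def build_synthetic_drm_lists(model: BetaVAE, vocab: Vocabulary,
                              min_count: int = 500, n_associates: int = 15,
                              min_length: int = 12) -> list[DrmList]:
    """DRM-like lists from the learned embedding.

    For every word with at least ``min_count`` corpus occurrences, the list
    candidate is its ``n_associates`` nearest embedding neighbours; rare
    associates (below ``min_count``) are removed and lists shorter than
    ``min_length`` discarded.
    """
    params = word_gen_params(model)
    counts = np.asarray(vocab.counts)
    out = []
    for qi in np.nonzero(counts >= min_count)[0]:
        lure = vocab.words[qi]
        assoc = nearest_associates(params, lure, vocab, k=n_associates)
        kept = tuple(w for w in assoc if vocab.count(w) >= min_count)
        if len(kept) < min_length:
            continue
        out.append(DrmList(lure=lure, studied=kept))
    return out


def random_word_list(vocab: Vocabulary, length: int, rng: np.random.Generator,
                     lure: str | None = None) -> DrmList:
    """A control list of uniformly random distinct vocabulary words."""
    pool = [w for w in vocab.words if w != lure]
    studied = tuple(rng.choice(len(pool), size=length, replace=False))
    words = tuple(pool[i] for i in studied)
    if lure is None:
        remaining = [w for w in vocab.words if w not in words]
        lure = remaining[int(rng.integers(len(remaining)))]
    return DrmList(lure=lure, studied=words)


def read_word_list(path) -> DrmList:
    """Plain-text list: first line the lure, following lines studied words."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError("word-list file needs a lure and at least one studied word")
    return DrmList(lure=lines[0], studied=tuple(lines[1:]))


def write_word_list(drm: DrmList, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join((drm.lure,) + drm.studied) + "\n")
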