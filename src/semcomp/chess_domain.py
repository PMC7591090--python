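"""The chess expertise experiment: encodings, model preset, datasets, scoring.

A board configuration is a 64-square position over 13 symbols (12 pieces +
empty) and is presented to the autoencoder as a 64x13 one-hot matrix.
Graded "expertise" is modelled by subsampling the pool of game positions to
increasing fractions; every skill level additionally sees 10000 uniformly
random boards, an uninformative inductive bias that dominates only in the
low-data regime.  Recall is scored both as the number of correctly placed
pieces (the classic board-reconstruction criterion) and as the fraction of
all 64 squares reproduced exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import chessrules as cr
from .bvae import BetaVAE, CategoricalGridLikelihood, TrainConfig
from .synthetic import GameRecord

__all__ = [
    "N_SQUARES",
    "N_SYMBOLS",
    "SkillDataset",
    "encode_board",
    "decode_board",
    "encode_boards",
    "build_chess_vae",
    "chess_train_config",
    "sample_uniform_board",
    "make_skill_datasets",
    "make_test_boards",
    "shuffle_board",
    "score_pieces",
    "score_squares",
    "DEFAULT_FRACTIONS",
    "DEFAULT_N_AUGMENT",
]

N_SQUARES = 64
N_SYMBOLS = 13  # 12 pieces + empty; class order follows chessrules.SYMBOLS

#: skill-level subsampling fractions of the full board pool
DEFAULT_FRACTIONS = (0.001, 0.01, 0.10, 0.90)
#: uniformly random boards added to every skill dataset
DEFAULT_N_AUGMENT = 10000


def encode_board(board) -> np.ndarray:
    """One-hot encode a board: row r is the symbol on square r; rows sum to 1."""
    arr = np.asarray(board, dtype=np.int64)
    if arr.shape != (N_SQUARES,):
        raise ValueError("board must have exactly 64 squares")
    if arr.min() < 0 or arr.max() >= N_SYMBOLS:
        raise ValueError("unknown piece symbol")
    out = np.zeros((N_SQUARES, N_SYMBOLS), dtype=np.float32)
    out[np.arange(N_SQUARES), arr] = 1.0
    return out


def decode_board(matrix: np.ndarray) -> tuple[int, ...]:
    """Per-square argmax symbol; ties break to the lowest symbol index."""
    arr = np.asarray(matrix, dtype=float)
    if arr.size != N_SQUARES * N_SYMBOLS:
        raise ValueError("expected a 64x13 matrix")
    return tuple(int(i) for i in arr.reshape(N_SQUARES, N_SYMBOLS).argmax(axis=1))


def encode_boards(boards) -> np.ndarray:
    """Stack of flattened one-hot encodings, shape (n, 832)."""
    return np.stack([encode_board(b).reshape(-1) for b in boards])


def chess_train_config(
    beta: float = 1e-4,
    seed: int = 0,
    preset: str = "desk",
    n_steps: int | None = None,
) -> TrainConfig:
    """Training configuration for the chess autoencoder.

    ``preset='full'`` uses the reference architecture (two 3000-unit sigmoid
    layers, 64 latent dimensions, Adam at 1e-4, batch 65); ``'desk'`` is the
    workstation-scale preset (512-unit layers, 32 latents, a larger learning
    rate to converge in few steps).  β defaults to 1e-4, small enough that
    the expert model operates in the near-verbatim regime.
    """
    if preset == "full":
        return TrainConfig(
            beta=beta, learning_rate=1e-4, batch_size=65,
            n_steps=20000 if n_steps is None else n_steps,
            seed=seed, latent_dim=64, hidden_widths=(3000, 3000),
        )
    if preset == "desk":
        return TrainConfig(
            beta=beta, learning_rate=1e-3, batch_size=65,
            n_steps=1200 if n_steps is None else n_steps,
            seed=seed, latent_dim=32, hidden_widths=(512,),
        )
    raise ValueError(f"unknown preset {preset!r}")


def build_chess_vae(config: TrainConfig) -> BetaVAE:
    """β-VAE over boards: categorical decoder with one 13-way factor per square."""
    return BetaVAE(
        input_dim=N_SQUARES * N_SYMBOLS,
        likelihood=CategoricalGridLikelihood(N_SQUARES, N_SYMBOLS),
        config=config,
    )


def sample_uniform_board(rng: np.random.Generator) -> tuple[int, ...]:
    """Each square independently uniform over the 13 symbols (legality ignored)."""
    return tuple(int(s) for s in rng.integers(0, N_SYMBOLS, size=N_SQUARES))


@dataclass(frozen=True)
class SkillDataset:
    """Subsampled game boards plus uniform augmentation for one skill level."""

    fraction: float
    boards: tuple
    n_augment: int


def _pool_boards(games) -> list[tuple[int, ...]]:
    pool: list[tuple[int, ...]] = []
    for g in games:
        pool.extend(g.boards)
    return pool


def make_skill_datasets(
    games: list[GameRecord],
    fractions=DEFAULT_FRACTIONS,
    n_augment: int = DEFAULT_N_AUGMENT,
    seed: int = 0,
) -> list[SkillDataset]:
    """Build one training set per skill fraction.

    All positions are pooled across games, subsampled without replacement to
    each fraction, and augmented with ``n_augment`` uniformly random boards.
    """
    if not games:
        raise ValueError("games must be non-empty")
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    pool = _pool_boards(games)
    rng = np.random.default_rng(seed)
    out = []
    for frac in fractions:
        k = int(round(frac * len(pool)))
        if k == 0:
            warnings.warn(f"fraction {frac} selects 0 boards; dataset is augmentation only")
        idx = rng.choice(len(pool), size=k, replace=False)
        boards = [pool[i] for i in idx]
        boards.extend(sample_uniform_board(rng) for _ in range(n_augment))
        out.append(SkillDataset(fraction=frac, boards=tuple(boards), n_augment=n_augment))
    return out


def make_test_boards(games: list[GameRecord], seed: int = 0
                     ) -> tuple[list[tuple[int, ...]], list[tuple[int, ...]]]:
    """Game- and random-condition test boards from held-out games.

    For each game a board is taken after full move 21 or 41 (chosen at
    random when both exist; games without move 41 fall back to 21; games
    shorter than 21 full moves are skipped).  The random condition applies
    ``shuffle_board`` to each game-condition board.
    """
    rng = np.random.default_rng(seed)
    game_cond: list[tuple[int, ...]] = []
    for g in games:
        full_moves = g.move_count // 2
        candidates = [m for m in (21, 41) if full_moves >= m]
        if not candidates:
            continue
        move = candidates[0] if len(candidates) == 1 else candidates[rng.integers(2)]
        game_cond.append(g.boards[2 * move])  # position after both sides moved
    if not game_cond:
        raise ValueError("no game long enough for a test board")
    random_cond = [shuffle_board(b, rng) for b in game_cond]
    return game_cond, random_cond


def shuffle_board(board, rng: np.random.Generator) -> tuple[int, ...]:
    """Permute piece identities uniformly across the occupied squares.

    Empty squares are untouched, so the occupied-square set and the piece
    multiset are conserved exactly — the structure-destroying 'random'
    condition of the recall experiment.
    """
    arr = np.asarray(board, dtype=np.int64).copy()
    occ = np.nonzero(arr)[0]
    if len(occ) == 0:
        raise ValueError("cannot shuffle a fully empty board")
    arr[occ] = arr[occ][rng.permutation(len(occ))]
    return tuple(int(v) for v in arr)


def score_pieces(original, reconstruction) -> int:
    """Number of originally placed pieces reproduced exactly (Gobet–Simon).

    Counts squares where the original holds a piece and the reconstruction
    carries the identical piece; pieces hallucinated onto originally empty
    squares do not count either way.
    """
    a = np.asarray(original, dtype=np.int64)
    b = np.asarray(reconstruction, dtype=np.int64)
    return int(np.sum((a != 0) & (a == b)))


def score_squares(original, reconstruction) -> float:
    """Fraction of all 64 squares (empties included) whose symbol matches."""
    a = np.asarray(original, dtype=np.int64)
    b = np.asarray(reconstruction, dtype=np.int64)
    return float(np.mean(a == b))
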