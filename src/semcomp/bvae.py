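"""Domain-agnostic β-VAE with explicit rate/distortion bookkeeping.

The model family: a diagonal-Gaussian amortised encoder q(z|x), a standard
Normal prior over the latent code, and a pluggable decoder likelihood
p(x|z).  Training maximises the β-weighted evidence lower bound, read
throughout as a rate-distortion objective

    loss = distortion + β · rate,

where the distortion is the negative reconstruction log-likelihood (one
reparameterised sample) and the rate is the closed-form KL divergence from
the posterior to the prior, both in nats per observation.  β is the
Lagrange multiplier of rate-distortion theory: large β buys a shorter code
(lower rate) at the price of higher distortion, which is how the package
models shrinking memory resources.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import DTYPE, MLP, Adam

__all__ = [
    "LatentPosterior",
    "TrainConfig",
    "RDPoint",
    "TrainingLog",
    "BetaVAE",
    "CategoricalGridLikelihood",
    "MultinomialLikelihood",
    "kl_diag_gaussian",
    "elbo_terms",
    "train",
    "reconstruct_map",
    "reconstruct_sample",
    "rd_point",
    "save_checkpoint",
    "load_checkpoint",
    "NotTrainedError",
    "TrainingDivergedError",
]

VARIANCE_FLOOR = 1e-6
_LOGVAR_MIN = float(np.log(VARIANCE_FLOOR))
_LOGVAR_MAX = 10.0

CHECKPOINT_VERSION = 1


class NotTrainedError(RuntimeError):
    """Raised when a reconstruction is requested from an untrained model."""


class TrainingDivergedError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"training diverged (non-finite loss) at step {step}")
        self.step = step


@dataclass(frozen=True)
class LatentPosterior:
    """Diagonal-Gaussian posterior over the latent code — the memory trace."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        variance = np.asarray(self.variance, dtype=float)
        if mean.shape != variance.shape:
            raise ValueError("mean and variance shapes differ")
        if not np.all(variance > 0):
            raise ValueError("posterior variances must be strictly positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "variance", variance)


@dataclass(frozen=True)
class TrainConfig:
    beta: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 100
    n_steps: int = 1000
    seed: int = 0
    latent_dim: int = 32
    hidden_widths: tuple[int, ...] = (256,)
    # plateau-based early stop on a held-out split; 0 disables it
    plateau_patience: int = 0
    plateau_check_every: int = 100
    plateau_tol: float = 1e-3
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.n_steps < 0:
            raise ValueError("invalid optimiser settings")
        if self.latent_dim < 1 or any(h < 1 for h in self.hidden_widths):
            raise ValueError("invalid architecture settings")
        object.__setattr__(self, "hidden_widths", tuple(self.hidden_widths))


@dataclass(frozen=True)
class RDPoint:
    """Location of a trained model on the rate-distortion plane (nats)."""

    rate: float
    distortion: float

    def __post_init__(self):
        if not (np.isfinite(self.rate) and np.isfinite(self.distortion)):
            raise ValueError("RD coordinates must be finite")
        if self.rate < -1e-9:
            raise ValueError("rate must be nonnegative")


@dataclass
class TrainingLog:
    loss: np.ndarray
    reconstruction: np.ndarray
    kl: np.ndarray
    beta: float
    stopped_at: int | None = None

    def check_invariant(self, rtol: float = 1e-6) -> bool:
        """loss[t] == reconstruction[t] + beta * kl[t] at every step."""
        expect = self.reconstruction.astype(np.float64) + self.beta * self.kl.astype(np.float64)
        scale = np.maximum(np.abs(expect), 1.0)
        return bool(np.all(np.abs(self.loss.astype(np.float64) - expect) <= rtol * scale))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "step": np.arange(len(self.loss)),
                "loss": self.loss,
                "reconstruction": self.reconstruction,
                "kl": self.kl,
            }
        ).to_csv(path, index=False)


def kl_diag_gaussian(posterior: LatentPosterior) -> float | np.ndarray:
    """KL( N(mean, diag(variance)) || N(0, I) ) in nats.

    Closed form per coordinate: (mu^2 + sigma^2 - 1 - ln sigma^2) / 2.
    Accepts a batch (last axis = latent dimension); returns a scalar for a
    single posterior.
    """
    mu = posterior.mean
    var = posterior.variance
    kl = 0.5 * np.sum(mu * mu + var - 1.0 - np.log(var), axis=-1)
    return float(kl) if kl.ndim == 0 else kl


# --- decoder likelihoods --------------------------------------------------


class CategoricalGridLikelihood:
    """Independent categorical distributions on a grid of factors.

    Used for chess boards: 64 factors with 13 classes each.  Observations
    are flattened one-hot arrays of length n_factors * n_classes.
    """

    def __init__(self, n_factors: int, n_classes: int):
        self.n_factors = n_factors
        self.n_classes = n_classes
        self.out_dim = n_factors * n_classes

    def _log_softmax(self, logits: np.ndarray) -> np.ndarray:
        l3 = logits.reshape(-1, self.n_factors, self.n_classes)
        m = l3.max(axis=-1, keepdims=True)
        lse = m + np.log(np.sum(np.exp(l3 - m), axis=-1, keepdims=True))
        return l3 - lse

    def log_likelihood(self, logits: np.ndarray, x: np.ndarray) -> np.ndarray:
        logp = self._log_softmax(logits)
        x3 = x.reshape(-1, self.n_factors, self.n_classes)
        return np.sum(logp * x3, axis=(1, 2))

    def nll_grad(self, logits: np.ndarray, x: np.ndarray) -> np.ndarray:
        """d(-log p(x|z)) / dlogits, same shape as logits."""
        p = np.exp(self._log_softmax(logits))
        x3 = x.reshape(-1, self.n_factors, self.n_classes)
        return (p - x3).reshape(-1, self.out_dim)

    def map_estimate(self, logits: np.ndarray) -> np.ndarray:
        """Per-factor mode (argmax class, lowest index on ties), one-hot."""
        l3 = logits.reshape(-1, self.n_factors, self.n_classes)
        idx = l3.argmax(axis=-1)
        out = np.zeros_like(l3)
        np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
        return out.reshape(-1, self.out_dim)

    def sample(self, logits: np.ndarray, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        p = np.exp(self._log_softmax(logits))
        cum = np.cumsum(p, axis=-1)
        u = rng.random(size=cum.shape[:-1] + (1,))
        idx = (u > cum).sum(axis=-1)
        out = np.zeros_like(p)
        np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
        return out.reshape(-1, self.out_dim)


class MultinomialLikelihood:
    """Bag-of-words likelihood: tokens iid from a softmax over the vocabulary.

    The document log-likelihood is the sum over tokens of ln p(word|z)
    (no multinomial coefficient), matching the independent word-generation
    process of the text model.
    """

    def __init__(self, vocab_size: int):
        self.vocab_size = vocab_size
        self.out_dim = vocab_size

    def _log_softmax(self, logits: np.ndarray) -> np.ndarray:
        m = logits.max(axis=-1, keepdims=True)
        return logits - (m + np.log(np.sum(np.exp(logits - m), axis=-1, keepdims=True)))

    def log_likelihood(self, logits: np.ndarray, x: np.ndarray) -> np.ndarray:
        return np.sum(self._log_softmax(logits) * x, axis=-1)

    def nll_grad(self, logits: np.ndarray, x: np.ndarray) -> np.ndarray:
        p = np.exp(self._log_softmax(logits))
        n = x.sum(axis=-1, keepdims=True)
        return n * p - x

    def map_estimate(self, logits: np.ndarray) -> np.ndarray:
        """Per-token mode: all tokens assigned to the argmax word.

        The total token count of the decoded document is tied to the input
        at reconstruction time by the caller.
        """
        idx = logits.argmax(axis=-1)
        out = np.zeros_like(logits)
        out[np.arange(len(idx)), idx] = 1.0
        return out

    def sample(self, logits: np.ndarray, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        p = np.exp(self._log_softmax(logits)).astype(np.float64)
        p /= p.sum(axis=-1, keepdims=True)
        n = x.sum(axis=-1).astype(int)
        out = np.empty_like(p)
        for i in range(len(p)):
            out[i] = rng.multinomial(n[i], p[i])
        return out.astype(logits.dtype)


# --- the model ------------------------------------------------------------


class BetaVAE:
    """Amortised-inference β-VAE over a pluggable decoder likelihood."""

    def __init__(
        self,
        input_dim: int,
        likelihood,
        config: TrainConfig,
        dec_hidden: tuple[int, ...] | None = None,
    ):
        self.input_dim = input_dim
        self.likelihood = likelihood
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = MLP(input_dim, list(config.hidden_widths), 2 * config.latent_dim, rng)
        dh = list(config.hidden_widths[::-1] if dec_hidden is None else dec_hidden)
        self.decoder = MLP(config.latent_dim, dh, likelihood.out_dim, rng)
        self.trained = False

    # -- inference ---------------------------------------------------------

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    @property
    def params(self) -> list[np.ndarray]:
        return self.encoder.params + self.decoder.params

    def _encode_raw(self, x: np.ndarray, cache: bool = False):
        out = self.encoder.forward(np.atleast_2d(np.asarray(x, dtype=DTYPE)), cache=cache)
        d = self.config.latent_dim
        mu = out[:, :d]
        raw_logvar = out[:, d:]
        logvar = np.clip(raw_logvar, _LOGVAR_MIN, _LOGVAR_MAX)
        return mu, logvar, raw_logvar

    def encode(self, x: np.ndarray) -> LatentPosterior:
        """Map observation(s) to the diagonal-Gaussian posterior q(z|x)."""
        self._check_dim(x)
        mu, logvar, _ = self._encode_raw(x)
        var = np.exp(logvar)
        if np.asarray(x).ndim == 1:
            return LatentPosterior(mu[0], var[0])
        return LatentPosterior(mu, var)

    def decode_logits(self, z: np.ndarray) -> np.ndarray:
        return self.decoder.forward(np.atleast_2d(np.asarray(z, dtype=DTYPE)), cache=False)

    def _check_dim(self, x: np.ndarray) -> None:
        x = np.asarray(x)
        if x.shape[-1] != self.input_dim:
            raise ValueError(
                f"observation dimension {x.shape[-1]} != model input {self.input_dim}"
            )

    # -- training step -----------------------------------------------------

    def _batch_terms(self, x: np.ndarray, rng: np.random.Generator, beta: float,
                     with_grad: bool):
        """One-sample ELBO terms averaged over the batch; optional backprop."""
        x = np.atleast_2d(np.asarray(x, dtype=DTYPE))
        B = x.shape[0]
        mu, logvar, raw_logvar = self._encode_raw(x, cache=with_grad)
        std = np.exp(0.5 * logvar)
        eps = rng.standard_normal(size=mu.shape).astype(DTYPE)
        z = mu + std * eps
        logits = self.decoder.forward(z, cache=with_grad)
        nll = -self.likelihood.log_likelihood(logits, x)
        kl_vec = 0.5 * np.sum(mu * mu + np.exp(logvar) - 1.0 - logvar, axis=-1)
        recon = float(nll.mean())
        rate = float(kl_vec.mean())
        loss = recon + beta * rate
        if with_grad:
            dlogits = self.likelihood.nll_grad(logits, x) / B
            dz = self.decoder.backward(dlogits)
            dmu = dz + beta * mu / B
            dlogvar = dz * (0.5 * std * eps) + beta * 0.5 * (np.exp(logvar) - 1.0) / B
            # clipped coordinates receive no gradient
            dlogvar = np.where(
                (raw_logvar > _LOGVAR_MIN) & (raw_logvar < _LOGVAR_MAX), dlogvar, 0.0
            ).astype(DTYPE)
            self.encoder.backward(np.concatenate([dmu, dlogvar], axis=1).astype(DTYPE))
        return recon, rate, loss


# --- the spec'd operations -------------------------------------------------


def elbo_terms(x: np.ndarray, model: BetaVAE, beta: float | None = None,
               rng: np.random.Generator | None = None) -> tuple[float, float, float]:
    """One-sample estimate of (reconstruction, rate, loss) for observation x.

    reconstruction = -E_{z~q}[ln p(x|z)] with a single reparameterised
    sample; rate = closed-form KL(q(z|x) || N(0,I)); loss is exactly
    reconstruction + beta * rate.
    """
    model._check_dim(x)
    beta = model.config.beta if beta is None else beta
    rng = np.random.default_rng(0) if rng is None else rng
    recon, rate, loss = model._batch_terms(x, rng, beta, with_grad=False)
    return recon, rate, loss


def train(model: BetaVAE, dataset: np.ndarray, config: TrainConfig | None = None
          ) -> tuple[BetaVAE, TrainingLog]:
    """Optimise the β-weighted ELBO with Adam; deterministic given the seed.

    The seed fixes both the (already applied) parameter initialisation and
    the batch/noise order here.  If ``plateau_patience`` > 0, a held-out
    split is monitored every ``plateau_check_every`` steps and training
    stops once its loss has not improved by ``plateau_tol`` for that many
    consecutive checks.
    """
    config = model.config if config is None else config
    data = np.asarray(dataset, dtype=DTYPE)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("dataset must be a non-empty 2-D array")
    model._check_dim(data)

    rng = np.random.default_rng(config.seed)
    val = None
    if config.plateau_patience > 0:
        n_val = max(1, int(round(config.val_fraction * len(data))))
        perm = rng.permutation(len(data))
        val, data = data[perm[:n_val]], data[perm[n_val:]]
        if len(data) == 0:
            raise ValueError("dataset too small for a validation split")

    opt = Adam(model.params, lr=config.learning_rate)
    losses, recons, kls = [], [], []
    best_val, stale, stopped_at = np.inf, 0, None
    val_rng = np.random.default_rng(config.seed + 1)
    for step in range(config.n_steps):
        idx = rng.integers(0, len(data), size=config.batch_size)
        recon, rate, loss = model._batch_terms(data[idx], rng, config.beta, with_grad=True)
        if not np.isfinite(loss):
            raise TrainingDivergedError(step)
        opt.step(model.encoder.grads + model.decoder.grads)
        losses.append(loss)
        recons.append(recon)
        kls.append(rate)
        if val is not None and (step + 1) % config.plateau_check_every == 0:
            _, _, vloss = model._batch_terms(
                val, np.random.default_rng(val_rng.integers(2**31)), config.beta, False
            )
            if vloss < best_val - config.plateau_tol:
                best_val, stale = vloss, 0
            else:
                stale += 1
                if stale >= config.plateau_patience:
                    stopped_at = step + 1
                    break
    model.trained = model.trained or config.n_steps > 0
    log = TrainingLog(
        loss=np.array(losses), reconstruction=np.array(recons), kl=np.array(kls),
        beta=config.beta, stopped_at=stopped_at,
    )
    return model, log


def _require_trained(model: BetaVAE) -> None:
    if not model.trained:
        raise NotTrainedError("model has not been trained")


def reconstruct_map(x: np.ndarray, model: BetaVAE) -> np.ndarray:
    """Deterministic recall: decode the posterior mean, take per-factor modes."""
    _require_trained(model)
    model._check_dim(x)
    x2 = np.atleast_2d(np.asarray(x, dtype=DTYPE))
    mu, _, _ = model._encode_raw(x2)
    out = model.likelihood.map_estimate(model.decode_logits(mu))
    return out[0] if np.asarray(x).ndim == 1 else out


def reconstruct_sample(x: np.ndarray, model: BetaVAE, n_samples: int,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """Stochastic recall: z ~ q(z|x), then an observation from p(x|z)."""
    _require_trained(model)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    model._check_dim(x)
    x2 = np.atleast_2d(np.asarray(x, dtype=DTYPE))
    mu, logvar, _ = model._encode_raw(x2)
    std = np.exp(0.5 * logvar)
    out = []
    for _ in range(n_samples):
        z = mu + std * rng.standard_normal(size=mu.shape).astype(DTYPE)
        logits = model.decode_logits(z)
        sample = model.likelihood.sample(logits, x2, rng)
        out.append(sample[0] if np.asarray(x).ndim == 1 else sample)
    return out


def rd_point(model: BetaVAE, dataset: np.ndarray, eval_seed: int = 0,
             batch_size: int = 512) -> RDPoint:
    """Locate the model on the RD plane for a dataset.

    rate = mean closed-form KL per observation; distortion = mean negative
    reconstruction log-likelihood per observation with a fixed evaluation
    seed (one posterior sample per item).
    """
    _require_trained(model)
    data = np.asarray(dataset, dtype=DTYPE)
    if data.ndim != 2 or len(data) == 0:
        raise ValueError("dataset must be a non-empty 2-D array")
    model._check_dim(data)
    rng = np.random.default_rng(eval_seed)
    tot_kl, tot_nll = 0.0, 0.0
    for start in range(0, len(data), batch_size):
        x = data[start:start + batch_size]
        mu, logvar, _ = model._encode_raw(x)
        std = np.exp(0.5 * logvar)
        z = mu + std * rng.standard_normal(size=mu.shape).astype(DTYPE)
        logits = model.decode_logits(z)
        tot_nll += float(-model.likelihood.log_likelihood(logits, x).sum())
        tot_kl += float(
            0.5 * np.sum(mu * mu + np.exp(logvar) - 1.0 - logvar)
        )
    n = len(data)
    return RDPoint(rate=tot_kl / n, distortion=tot_nll / n)


# --- checkpoints ----------------------------------------------------------


def save_checkpoint(model: BetaVAE, path) -> None:
    """Single-file checkpoint: parameters plus the embedded TrainConfig."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "input_dim": model.input_dim,
        "trained": model.trained,
        "likelihood": type(model.likelihood).__name__,
        "likelihood_args": (
            [model.likelihood.n_factors, model.likelihood.n_classes]
            if isinstance(model.likelihood, CategoricalGridLikelihood)
            else [model.likelihood.vocab_size]
        ),
        "dec_hidden": [layer.W.shape[0] for layer in model.decoder.layers[1:]],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(model.config).items()
        },
    }
    arrays = {f"p{i}": p for i, p in enumerate(model.params)}
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path) -> BetaVAE:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = meta["config"]
        cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
        config = TrainConfig(**cfg)
        if meta["likelihood"] == "CategoricalGridLikelihood":
            lik = CategoricalGridLikelihood(*meta["likelihood_args"])
        else:
            lik = MultinomialLikelihood(*meta["likelihood_args"])
        model = BetaVAE(meta["input_dim"], lik, config,
                        dec_hidden=tuple(meta["dec_hidden"]) or None)
        for i, p in enumerate(model.params):
            p[...] = npz[f"p{i}"]
        model.trained = meta["trained"]
    return model
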