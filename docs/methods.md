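# Methods

## Model

All analyses use the same model family: a β-variational autoencoder with a
diagonal-Gaussian amortised encoder q(z|x) = N(μ(x), diag σ²(x)), a
standard-Normal prior over the latent code, and a domain-specific decoder
likelihood p(x|z).  Training minimises

    loss = D + β·R,
    D = −E_{z∼q}[ln p(x|z)]   (one reparameterised sample per estimate),
    R = KL(q(z|x) ‖ N(0,I))   (closed form),

by Adam on minibatches.  The identification of the reconstruction term
with distortion and the KL term with rate makes every trained model a
point on the rate-distortion plane; β is the local slope of the trade-off
and is the package's model of available memory resources (large β = strong
compression = long retention interval).

Encoding an observation and keeping only the posterior is the memory
trace; recall is decoding, either deterministically (decode the posterior
mean and take each output factor's mode — "MAP recall") or by sampling
z ∼ q(z|x), x̂ ∼ p(x|z).

### Decoders

* **Chess**: 64 independent 13-way categorical distributions, one per
  square (12 pieces + empty).  Boards enter as flattened 64×13 one-hot
  matrices.
* **Text**: documents are bags of words; tokens are generated
  independently through a linear map of the decoder's last hidden
  activations followed by a softmax, eᵢ = exp(−zᵀR xᵢ + b), p(xᵢ|z) =
  eᵢ/Σⱼeⱼ.  The columns of R are the semantic word embedding used to
  construct associate lists.  The document log-likelihood is the sum of
  per-token log-probabilities (no multinomial coefficient).  The printed
  minus sign is kept as-is; it is equivalent to the unsigned form under
  R → −R and has no behavioural consequence.

### Numerical choices

* Posterior variances are floored at 1e-6 (log-variance clipped at both
  ends, clipped coordinates receive zero gradient) — numerical safety far
  below any behaviourally relevant scale.
* One reparameterised sample per ELBO estimate; float32 throughout;
  Xavier-style initialisation fixed by the config seed.  Every operation
  that takes a seed is bitwise reproducible.
* Training draws batches with replacement; a plateau-based early stop on a
  held-out split is available (off by default so step counts are exactly
  reproducible across configurations).
* MAP decoding breaks probability ties towards the lower symbol index.
* Distinct-word recall uses sequential sampling without replacement with
  renormalisation after each draw; the constraint (not the mechanism) is
  the modelling commitment.

## Architectures and presets

Reference architectures: chess — two 3000-unit sigmoid layers in encoder
and decoder, 64 latent dimensions, Adam 1e-4, batch 65, β = 1e-4; text —
two 2000-unit layers, 100 latents, Adam 1e-5, batch 100.  These sizes are
impractical for a quick CPU run, so each domain also has a **desk preset**
used by the tests, examples and the acceptance script:

| preset      | hidden | latent | lr   | steps | batch |
|-------------|--------|--------|------|-------|-------|
| chess desk  | 512    | 32     | 1e-3 | 1200  | 65    |
| text desk   | 256    | 32     | 1e-3 | 2000  | 100   |

The desk learning rates are larger than the reference values because the
networks are ~6× narrower and train for far fewer steps; the qualitative
pattern survives width reduction (accuracy saturates at a lower
piece count, as expected for reduced capacity).  β defaults keep their
reference values: 1e-4 (chess), 0.5 (text list-construction model).

## Synthetic data

**Text.**  A Latent Dirichlet Allocation corpus: topic-word distributions
φ_k ~ Dir(0.1) drawn once, per-document θ ~ Dir(0.1), tokens iid from
Σ_k θ_k φ_k.  Reference scale: V = 1000, K = 10, 20000 documents; desk
scale: V = 300, K = 6, 4000 documents.  Documents are fixed at 40 tokens
(matching the 40-word excerpt length of the real-text setting; the length
distribution is otherwise a free choice).  The concentrations 0.1 make
documents dominated by a few topics — separable but not perfectly, which
the topic-separability test verifies by clustering.  What this generator
does **not** emulate: Zipfian word frequencies, syntax, word order,
polysemy.  Passing tests therefore show that the *mechanism* (gist-based
intrusion under compression) operates under controlled topical statistics,
not that the model reproduces human lexical behaviour.

**Chess.**  Games are played by choosing uniformly at random among legal
moves from the standard start, until mate/stalemate/insufficient material
or 80 plies.  Positions therefore lie on the legal-game manifold — the
property the expertise analysis exploits — but their statistics differ
from human play (no plans, rare captures of purpose, long shuffling
endgames).  The generator is a stated surrogate whose job is the
structure-vs-shuffle contrast, not chess realism.  An independent
structural legality checker (king counts, pawn ranks, piece-count bounds,
king adjacency) oracles every emitted position in the tests.

**DRM lists.**  For each vocabulary word frequent enough in the corpus,
the candidate list is its 15 nearest embedding associates (cosine over
columns of R, ties to the lower index); infrequent associates are removed
and lists shorter than 12 discarded.  The count floor is 500 occurrences
at the reference corpus size of 800k tokens; the desk corpus has 160k
tokens, so the desk default floor is 100 — the same relative frequency.
With the absolute floor of 500 the desk corpus yields no lists at all
(a scale artifact: only ~5 of 15 associates clear it).

## Experiments

**Expertise.**  The pooled positions of ~2000 synthetic games are split
90/10 by game (held-out test games are never subsampled), subsampled to
fractions 0.001/0.01/0.1/0.9, and each skill level is augmented with
10000 uniformly random boards — an uninformative inductive bias that
dominates only in the low-data regime.  "Uniformly random" is read
literally as iid-uniform symbols per square (illegal boards included),
since the augmentation's purpose is a uniform prior over the whole
configuration space.  Test boards are taken after full move 21 or 41
(games shorter than 21 full moves are skipped; shorter than 41 fall back
to 21; "move" means full move, not ply).  Recall is scored as the number
of originally placed pieces reproduced exactly (hallucinated pieces on
empty squares are not counted — square accuracy captures those) and as
the fraction of all 64 squares correct.

**DRM / calibration.**  Recall of a word = membership of the sampled
reconstruction list (100 samples per list; sampled lists have exactly the
studied-list length).  β for "immediate recall" is calibrated on a grid
(0.1–10) to minimise |mean lure − mean studied| recall.  Because both
recalls collapse towards zero at very high β, making the gap trivially
small, the argmin is restricted to grid points whose studied recall is at
least half the grid maximum, with ties to the smaller β: the condition
being matched has substantial, approximately equal recall for both word
types.  Control lists of uniformly random vocabulary words (same lengths)
quantify the coherence advantage.

**Forgetting sweep.**  One independent model per β (no annealed
fine-tuning), three seeds per cell by default; the per-β tables record
mean studied recall, mean lure recall, their difference, and the measured
(rate, distortion) on a corpus subsample.  Default grids are logarithmic
around the calibrated β.  The mapping from β to physical delay is not
derivable from the theory and is deliberately left uncalibrated.

## Known limitations

* The β-VAE is numpy-based and desk-scale; reference-scale architectures
  are configurable but slow on one CPU.
* Ordinal claims only on the RD plane: no numeric RD coordinates are
  targets, and distortion units are nats of negative log-likelihood by
  package convention.
* No sequential structure in text, no explicit chess rules in the model,
  no human-data curve fitting, no β↔delay calibration, and no
  hierarchical/multi-rate single-model variant.
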