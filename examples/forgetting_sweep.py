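"""Forgetting as optimal compression: recall along a β sweep.

Trains an independent bag-of-words model at each point of a β grid and
measures studied-word and lure recall on synthetic DRM lists, together
with the model's position on the rate-distortion plane.  Rising β stands
for lengthening retention interval: memory traces are re-encoded at ever
lower rate.
"""

from semcomp.experiments import DrmConfig, SweepConfig, prepare_text_data, \
    run_forgetting_sweep
from semcomp.synthetic import LdaParams

drm = DrmConfig(
    lda=LdaParams(vocab_size=300, n_topics=6, n_docs=4000, seed=0),
    seeds=(0,),
    max_lists=15,
)
config = SweepConfig(beta_grid=(0.05, 0.2, 0.8, 3.2, 12.8), seeds=(0,), drm=drm)
data = prepare_text_data(drm)
recall, rd = run_forgetting_sweep(config, data=data)

merged = recall.merge(rd, on=["beta", "seed"])
print("recall and rate along the compression sweep:\n")
print(
    merged[["beta", "mean_studied", "mean_lure", "difference", "rate"]]
    .round(3).to_string(index=False)
)
print(
    "\nStudied recall falls monotonically as β grows (less memory per "
    "trace).\nLure recall persists — the gist outlives the details — until "
    "very high\ncompression erases even the gist.  The rate column shows "
    "the shrinking\nnats-per-document budget that drives the change."
)
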