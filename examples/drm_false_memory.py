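"""False memory for word lists: the lure intrudes into sampled recall.

Generates a synthetic topic-model corpus, trains the bag-of-words
autoencoder, builds DRM-style lists (each list = the nearest embedding
associates of a frequent 'lure' word, which itself is never studied), and
estimates recall frequencies from 100 sampled reconstructions per list.

A gist-based memory should recall the never-shown lure about as often as
the words actually studied.
"""

from dataclasses import replace

import numpy as np

from semcomp.experiments import DrmConfig, prepare_text_data, run_drm
from semcomp.synthetic import LdaParams

config = DrmConfig(
    lda=LdaParams(vocab_size=300, n_topics=6, n_docs=4000, seed=0),
    seeds=(0,),
    beta=0.1,      # near the calibrated immediate-recall point
    max_lists=15,
)
data = prepare_text_data(config)
words, summary, beta = run_drm(config, data=data)

row = summary.iloc[0]
print(f"{row['n_lists']} synthetic DRM lists, beta = {beta}\n")
print(f"mean studied-word recall : {row['mean_studied']:.3f}")
print(f"mean lure recall         : {row['mean_lure']:.3f}")
print(f"random-word-list recall  : {row['mean_random_list']:.3f}\n")

one = words[words["list_id"] == 0].sort_values("recall_frequency",
                                               ascending=False)
print("one list in detail (lure marked *):")
for _, r in one.iterrows():
    mark = "*" if r["role"] == "lure" else " "
    print(f"  {mark} {r['word']:8s} {r['recall_frequency']:.2f}")
print(
    "\nThe lure was never presented, yet its recall frequency is comparable "
    "to the\nstudied words — a gist-based intrusion.  Topically coherent "
    "lists are recalled\nbetter than random-word lists of the same length."
)
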