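"""Chromatin-type calling from histone-mark tracks, end to end on synthetic data.

Generates a blocky chromatin-type sequence, emits 11 histone-mark signal
tracks from it, bins the tracks to 50 kb, discretizes to 20 signal states,
fits the windowed surrogate predictor and calls types back.  The printed
accuracy is the fraction of loci whose call matches the generating label.
"""

import numpy as np

from chromoscape import (bin_signal, discretize, fit_surrogate_predictor,
                         gen_chipseq_tracks, gen_type_sequence, predict_types,
                         type_frequency_profile)
from chromoscape.synthetic import default_emission_model

n_loci = 2000
types = gen_type_sequence(n_loci, mean_block_len=20, seed=1)
tracks = gen_chipseq_tracks(types, default_emission_model(), seed=2)
binned = {mark: bin_signal(t, chrom_length=n_loci * 50_000)
          for mark, t in tracks.items()}
disc = discretize(binned)
predictor = fit_surrogate_predictor(disc, types)
called = predict_types(predictor, disc)

accuracy = np.mean(called.labels == types.labels)
print(f"loci: {n_loci}, marks: {len(disc.marks)}")
print(f"type-calling accuracy vs generating labels: {accuracy:.1%}")
# per-locus frequency profile across 'cell types' (here: two seeds)
other = predict_types(fit_surrogate_predictor(disc, types, pseudocount=5), disc)
profile = type_frequency_profile([called, other])
print("first five loci of the type-frequency profile:")
print(profile.head())
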