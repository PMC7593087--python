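"""Binning, 20-state discretization, surrogate type calling."""

import numpy as np
import pytest

from chromoscape.chipseq import (CHROMATIN_TYPES, BinnedTrack,
                                 ChromatinTypeSequence, SignalTrack,
                                 bin_signal, discretize,
                                 fit_surrogate_predictor, predict_types,
                                 type_frequency_profile)
from chromoscape.errors import ConfigurationError, InvalidArgumentError
from chromoscape.synthetic import (default_emission_model, gen_chipseq_tracks,
                                   gen_type_sequence)


def _track(intervals, mark="H3K27ac", chrom="chrT"):
    s, e, v = zip(*intervals)
    return SignalTrack(chrom=chrom, starts=np.array(s), ends=np.array(e),
                       values=np.array(v, dtype=float), mark_name=mark)


class TestBinSignal:
    def test_interval_matching_bin(self):
        binned = bin_signal(_track([(0, 50_000, 3.0)]), chrom_length=150_000)
        assert np.allclose(binned.values, [3.0, 0.0, 0.0])

    def test_proportional_split_at_boundary(self):
        binned = bin_signal(_track([(25_000, 75_000, 4.0)]),
                            chrom_length=100_000)
        assert np.allclose(binned.values, [2.0, 2.0])

    def test_empty_track_all_zero(self):
        binned = bin_signal(_track([(0, 1, 0.0)]), chrom_length=100_000)
        assert np.allclose(binned.values, 0.0)

    def test_total_signal_conserved(self, rng):
        starts = np.arange(0, 200_000, 1000)
        vals = rng.random(len(starts))
        binned = bin_signal(_track(list(zip(starts, starts + 900, vals))),
                            chrom_length=200_000)
        assert np.isclose(binned.values.sum(), vals.sum())


class TestDiscretize:
    def test_top_five_percent_get_state_20(self):
        binned = {"m": BinnedTrack(values=np.arange(1.0, 101.0))}
        disc = discretize(binned)
        assert np.array_equal(np.where(disc.states[:, 0] == 20)[0],
                              np.arange(95, 100))

    def test_degenerate_constant_signal_warns_all_20(self):
        binned = {"m": BinnedTrack(values=np.zeros(50))}
        with pytest.warns(UserWarning):
            disc = discretize(binned)
        assert np.all(disc.states == 20)

    def test_linear_partition_arithmetic(self):
        # min 0, 95th-percentile threshold 19 -> width 1, value 9.5 -> state 10
        values = np.concatenate([np.linspace(0, 18.99, 95), np.full(5, 19.0)])
        values[50] = 9.5
        disc = discretize({"m": BinnedTrack(values=values)})
        assert disc.states[50, 0] == 10

    def test_state_ordering_preserves_signal_ordering(self, rng):
        values = rng.exponential(size=500)
        disc = discretize({"m": BinnedTrack(values=values)})
        order = np.argsort(values)
        assert np.all(np.diff(disc.states[order, 0]) >= 0)

    def test_top_state_occupancy_at_least_five_percent(self, rng):
        values = np.round(rng.exponential(size=1000), 1)  # heavy ties
        disc = discretize({"m": BinnedTrack(values=values)})
        assert (disc.states[:, 0] == 20).sum() >= 0.05 * 1000


def _synthetic_discretized(n_loci=3000, spread=0.75, seed=11):
    types = gen_type_sequence(n_loci, seed=seed)
    tracks = gen_chipseq_tracks(types, default_emission_model(spread),
                                seed=seed + 1)
    binned = {m: bin_signal(t, chrom_length=n_loci * 50_000)
              for m, t in tracks.items()}
    return types, discretize(binned)


class TestPredictor:
    def test_deterministic_emissions_recovered_exactly(self):
        # one-hot emissions: the centre locus alone identifies the type
        types, disc = _synthetic_discretized(spread=0.0)
        pred = fit_surrogate_predictor(disc, types, window_halfwidth=0)
        called = predict_types(pred, disc)
        assert np.mean(called.labels == types.labels) == 1.0

    def test_accuracy_at_default_spread(self):
        types, disc = _synthetic_discretized()
        pred = fit_surrogate_predictor(disc, types)
        called = predict_types(pred, disc)
        assert np.mean(called.labels == types.labels) >= 0.90

    def test_accuracy_decreases_with_spread(self):
        accs = {}
        for spread in (0.5, 4.0):
            types, disc = _synthetic_discretized(spread=spread)
            pred = fit_surrogate_predictor(disc, types)
            called = predict_types(pred, disc)
            accs[spread] = np.mean(called.labels == types.labels)
        assert accs[0.5] > accs[4.0]

    def test_large_pseudocount_tends_uniform(self):
        types, disc = _synthetic_discretized(n_loci=500)
        pred = fit_surrogate_predictor(disc, types, pseudocount=1e9)
        tables = np.exp(pred.log_cond)
        assert np.allclose(tables, 1.0 / 20, atol=1e-4)

    def test_uniform_predictor_breaks_ties_to_first_type(self):
        from chromoscape.chipseq import TypePredictor
        types, disc = _synthetic_discretized(n_loci=200)
        n_marks = len(disc.marks)
        pred = TypePredictor(
            marks=disc.marks,
            log_cond=np.full((5, n_marks, 5, 20), np.log(1 / 20)),
            log_prior=np.full(5, np.log(0.2)))
        called = predict_types(pred, disc)
        assert set(called.labels) == {"A1"}

    def test_na_mask_applied(self):
        types, disc = _synthetic_discretized(n_loci=200)
        pred = fit_surrogate_predictor(disc, types)
        mask = np.zeros(200, dtype=bool)
        mask[:10] = True
        called = predict_types(pred, disc, na_mask=mask)
        assert set(called.labels[:10]) == {"NA"}

    def test_mark_mismatch_rejected(self):
        types, disc = _synthetic_discretized(n_loci=200)
        pred = fit_surrogate_predictor(disc, types)
        from chromoscape.chipseq import DiscretizedTracks
        swapped = DiscretizedTracks(states=disc.states,
                                    marks=tuple(reversed(disc.marks)))
        with pytest.raises(ConfigurationError):
            predict_types(pred, swapped)

    def test_json_round_trip(self, tmp_path):
        types, disc = _synthetic_discretized(n_loci=300)
        pred = fit_surrogate_predictor(disc, types)
        path = tmp_path / "predictor.json"
        pred.to_json(path)
        from chromoscape.chipseq import TypePredictor
        back = TypePredictor.from_json(path)
        a = predict_types(pred, disc).labels
        b = predict_types(back, disc).labels
        assert np.array_equal(a, b)


class TestTypeFrequencyProfile:
    def test_identical_annotations_one_hot(self):
        seq = gen_type_sequence(50, seed=1)
        prof = type_frequency_profile([seq] * 4)
        assert np.allclose(prof.to_numpy().sum(axis=1), 1.0)
        assert np.allclose(prof.to_numpy().max(axis=1), 1.0)

    def test_single_disagreement_half_half(self):
        a = ChromatinTypeSequence(labels=np.array(["A1"] * 10, dtype=object))
        labels = np.array(["A1"] * 10, dtype=object)
        labels[3] = "B2"
        b = ChromatinTypeSequence(labels=labels)
        prof = type_frequency_profile([a, b])
        assert prof.loc[3, "A1"] == 0.5
        assert prof.loc[3, "B2"] == 0.5

    def test_random_annotations_near_uniform(self, rng):
        n_inputs, n_loci = 400, 30
        seqs = [ChromatinTypeSequence(labels=rng.choice(
            np.array(CHROMATIN_TYPES, dtype=object), size=n_loci))
            for _ in range(n_inputs)]
        prof = type_frequency_profile(seqs)
        se = np.sqrt(0.2 * 0.8 / n_inputs)
        assert np.all(np.abs(prof[list(CHROMATIN_TYPES)].to_numpy() - 0.2)
                      < 3.5 * se)

    def test_length_mismatch_rejected(self):
        a = ChromatinTypeSequence(labels=np.array(["A1"] * 5, dtype=object))
        b = ChromatinTypeSequence(labels=np.array(["A1"] * 6, dtype=object))
        with pytest.raises(InvalidArgumentError):
            type_frequency_profile([a, b])
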