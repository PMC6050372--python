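"""Shared fixtures: small, fast synthetic objects.

Unit tests run on reduced geometries (8-16 channels, short tasks); the
acceptance tests in test_acceptance.py use the full default geometry.
"""

import dataclasses

import numpy as np
import pytest

import megbmi as m


@pytest.fixture(scope="session")
def small_subject():
    """16-channel subject at the default design point."""
    return m.make_subject(seed=11, n_channels=16)


@pytest.fixture(scope="session")
def small_schedule():
    return m.make_offline_schedule(8, seed=21)


@pytest.fixture(scope="session")
def small_offline(small_subject, small_schedule):
    rec = m.simulate_offline_task(small_subject, small_schedule, seed=31)
    stats = m.fit_baseline_stats(rec)
    series = m.sliding_features(rec, stats)
    epochs = m.epoch_features(series, small_schedule.cue_times_ms,
                              small_schedule.labels)
    return rec, stats, series, epochs


@pytest.fixture(scope="session")
def small_decoder(small_subject, small_offline):
    """Real decoder trained and threshold-calibrated on the small subject."""
    rec, stats, _, epochs = small_offline
    dec = m.make_real_decoder(epochs, rec, stats, seed=41)
    rest = m.simulate_rest(small_subject, 60, seed=51)
    onset = m.calibrate_threshold(dec.onset, rest, stats, 2.0)
    return dataclasses.replace(dec, onset=onset), stats


@pytest.fixture(scope="session")
def small_session(small_subject, small_decoder):
    decoder, stats = small_decoder
    log, after = m.run_training_session(small_subject, decoder, stats,
                                        duration_s=120.0, seed=61)
    return log, after, decoder, stats


def toy_epochs(n_per_class=6, n_offsets=5, n_channels=3, effect_offset=None,
               effect=2.0, seed=0, offsets_ms=None):
    """Gaussian toy epochs with an optional class effect at one offset."""
    rng = np.random.default_rng(seed)
    if offsets_ms is None:
        offsets_ms = np.arange(0, n_offsets * 100, 100, dtype=np.int64)
    n = 2 * n_per_class
    data = rng.standard_normal((n, n_offsets, n_channels))
    labels = ["grasp"] * n_per_class + ["open"] * n_per_class
    if effect_offset is not None:
        k = int(np.nonzero(offsets_ms == effect_offset)[0][0])
        data[:n_per_class, k, :] += effect
        data[n_per_class:, k, :] -= effect
    return m.EpochFeatures(data=data, offsets_ms=np.asarray(offsets_ms),
                           labels=labels)
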