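import numpy as np
import pytest
from scipy.signal import periodogram

from nirsbci.montage import Montage
from nirsbci.optics import OpticsParameters
from nirsbci.simulate import (
    EffectSpec,
    NoiseSpec,
    ParticipantSpec,
    ProtocolError,
    generate_protocol,
    hemodynamics_to_intensity,
    noise_series,
    sample_exclusions,
    simulate_hemodynamics,
    simulate_participants,
)


@pytest.fixture(scope="module")
def schedule():
    return generate_protocol(seed=5)


class TestProtocol:

    def test_each_task_occurs_sixty_times(self, schedule):
        counts = schedule[schedule.phase == "task"].task.value_counts()
        assert set(counts) == {60}
        assert len(counts) == 6

    def test_24_task_intervals_per_block(self, schedule):
        per_block = schedule[schedule.phase == "task"].groupby(
            ["session", "block"]).size()
        assert (per_block == 24).all()

    def test_task_counts_exact_within_each_block(self, schedule):
        per = schedule[schedule.phase == "task"].groupby(
            ["session", "block"]).task.value_counts()
        assert set(per) == {4}

    def test_block_duration_is_918_seconds(self, schedule):
        block = schedule[(schedule.session == 0) & (schedule.block == 0)]
        assert (block.onset_s + block.duration_s).max() == pytest.approx(918.0)
        next_block = schedule[(schedule.session == 0) & (schedule.block == 1)]
        assert next_block.onset_s.min() == pytest.approx(918.0)

    def test_deterministic_under_seed(self, schedule):
        again = generate_protocol(seed=5)
        assert schedule.equals(again)
        assert not schedule.equals(generate_protocol(seed=6))

    def test_randomization_is_within_block(self):
        sched = generate_protocol(n_sessions=2, seed=9)
        orders = sched[sched.phase == "task"].groupby(
            ["session", "block"]).task.apply(tuple)
        assert len(set(orders)) > 1  # blocks differ ...
        for o in orders:  # ... but each is a 4-of-each-task multiset
            assert all(o.count(t) == 4 for t in set(o))

    def test_non_divisible_layout_rejected(self):
        with pytest.raises(ProtocolError):
            generate_protocol(tasks=("A", "A"), seed=0)


class TestHemodynamics:
    def test_zero_effects_zero_noise_gives_zero(self, montage):
        sched = generate_protocol(n_sessions=1, n_blocks=1, seed=0)
        eff = EffectSpec(
            signatures={t: np.zeros(9) for t in "MM WG HT RF RS RR".split()},
            trial_noise_uM=0.0, amplitude_jitter=0.0,
        )
        recs = simulate_hemodynamics(sched, eff, NoiseSpec.silent(), montage, seed=0)
        np.testing.assert_array_equal(recs[0].data, 0.0)

    def test_same_seed_bit_identical(self, montage):
        sched = generate_protocol(n_sessions=1, n_blocks=1, seed=1)
        a = simulate_hemodynamics(sched, EffectSpec(), NoiseSpec(), montage, seed=3)
        b = simulate_hemodynamics(sched, EffectSpec(), NoiseSpec(), montage, seed=3)
        np.testing.assert_array_equal(a[0].data, b[0].data)

    def test_thb_exactly_sum(self, montage):
        sched = generate_protocol(n_sessions=1, n_blocks=1, seed=2)
        rec = simulate_hemodynamics(sched, EffectSpec(), NoiseSpec(), montage,
                                    seed=4)[0]
        np.testing.assert_array_equal(rec.data[:, 2],
                                      rec.data[:, 0] + rec.data[:, 1])

    def test_cardiac_peak_at_nominal_frequency(self, montage):
        sched = generate_protocol(n_sessions=1, n_blocks=1, seed=0)
        noise = NoiseSpec(mayer_uM=0, resp_uM=0, drift_uM=0, white_uM=0,
                          cardiac_uM=0.2, cardiac_hz=1.1)
        eff = EffectSpec(
            signatures={t: np.zeros(9) for t in "MM WG HT RF RS RR".split()},
            trial_noise_uM=0.0,
        )
        rec = simulate_hemodynamics(sched, eff, noise, montage, seed=6)[0]
        f, p = periodogram(rec.data[0, 0], fs=rec.fs)
        peak = f[np.argmax(p)]
        assert abs(peak - 1.1) <= f[1] - f[0]

    def test_noise_components_regenerable_and_additive(self):
        noise = NoiseSpec()
        full = noise_series(noise, 1000, 31.25, seed=9, session=0, channel=2)
        parts = sum(
            noise_series(noise, 1000, 31.25, seed=9, session=0, channel=2,
                         component=c)
            for c in ("mayer", "resp", "cardiac", "drift", "white")
        )
        np.testing.assert_allclose(full, parts, atol=1e-12)

    def test_fs_must_resolve_cardiac(self, montage):
        sched = generate_protocol(n_sessions=1, n_blocks=1, seed=0)
        with pytest.raises(ProtocolError):
            simulate_hemodynamics(sched, EffectSpec(), NoiseSpec(), montage, fs=2.0)


class TestParticipants:
    def test_likert_within_bounds(self):
        profiles, _ = simulate_participants(ParticipantSpec(n_participants=200), seed=0)
        for item in ("tiredness", "concentration", "enjoyment",
                     "ease_of_session", "headgear_comfort"):
            assert profiles[item].between(1, 7).all()

    def test_zero_coupling_decorrelates_iq_and_scale(self):
        spec = ParticipantSpec(n_participants=200, iq_coupling=0.0)
        profiles, scales = simulate_participants(spec, seed=1)
        r = np.corrcoef(profiles.verbal_iq, scales)[0, 1]
        assert abs(r) < 0.3

    def test_negative_coupling_gives_negative_spearman(self):
        from scipy.stats import spearmanr

        spec = ParticipantSpec(n_participants=200, iq_coupling=-0.5)
        profiles, scales = simulate_participants(spec, seed=1)
        rho, _ = spearmanr(profiles.verbal_iq, scales)
        assert rho < -0.5

    def test_missing_iq(self):
        spec = ParticipantSpec(n_participants=10, missing_iq=3)
        profiles, _ = simulate_participants(spec, seed=2)
        assert profiles.verbal_iq.isna().sum() == 1


class TestExclusions:
    def test_at_most_four_per_class(self):
        sched = generate_protocol(seed=0)
        excl = sample_exclusions(sched, seed=1)
        if len(excl):
            assert excl.task.value_counts().max() <= 4
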