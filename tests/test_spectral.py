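import numpy as np
import pandas as pd
import pytest

import topospect as ts
from topospect.recording import ConditionSpan, Recording, Span
from topospect.spectral import (BandDef, SpectralError, band_difference,
                                band_power, propose_bands,
                                reject_artifact_windows, segment_windows,
                                welch_psd)

FS = 250.0


def _rec(seconds, blocks=None, artifacts=()):
    n = int(seconds * FS)
    data = np.random.default_rng(0).normal(size=(2, n))
    blocks = blocks or [ConditionSpan(0.0, seconds, "NC", "NDE", "PE")]
    return Recording(data=data, sfreq=FS, channel_ids=["E1", "E2"],
                     condition_annotations=blocks,
                     artifact_annotations=list(artifacts))


class TestSegmentation:
    @pytest.mark.parametrize("seconds,expected", [(300, 10), (299, 9),
                                                  (1200, 40)])
    def test_window_counts(self, seconds, expected):
        assert len(segment_windows(_rec(seconds))) == expected

    def test_too_short_recording_yields_empty(self):
        assert segment_windows(_rec(10)) == []

    def test_windows_carry_block_labels(self):
        blocks = [ConditionSpan(0, 60, "NC", "NDE", "PE"),
                  ConditionSpan(60, 60, "HY", "AUTOBIO", "KS")]
        wins = segment_windows(_rec(120, blocks))
        assert [w.state for w in wins] == ["NC", "NC", "HY", "HY"]
        assert [w.memory for w in wins] == ["NDE", "NDE", "AUTOBIO", "AUTOBIO"]


class TestArtifactRejection:
    @pytest.mark.parametrize("artifact_s,kept", [(5.0, True), (5.2, False)])
    def test_five_second_rule_is_strict(self, artifact_s, kept):
        wins = segment_windows(_rec(30))
        retained, rejected = reject_artifact_windows(
            wins, [Span(2.0, artifact_s)])
        assert (len(retained) == 1) is kept
        assert len(retained) + len(rejected) == 1

    def test_no_artifacts_keeps_everything(self):
        wins = segment_windows(_rec(300))
        retained, rejected = reject_artifact_windows(wins, [])
        assert len(retained) == len(wins) and not rejected

    def test_window_count_conservation(self):
        wins = segment_windows(_rec(300, artifacts=[Span(10, 20), Span(100, 3)]))
        retained, rejected = reject_artifact_windows(
            wins, [Span(10, 20), Span(100, 3)])
        assert len(retained) + len(rejected) == len(wins)


class TestWelch:
    def test_sinusoid_power_concentrated_at_its_bin(self):
        t = np.arange(0, 30, 1 / FS)
        freqs, psd = welch_psd(np.sin(2 * np.pi * 10 * t), FS)
        assert freqs[np.argmax(psd[0])] == pytest.approx(10.0)
        # integrated power of a unit sinusoid is amplitude^2/2 = 0.5
        total = psd[0].sum() * (freqs[1] - freqs[0])
        assert total == pytest.approx(0.5, rel=0.05)

    def test_white_noise_spectrum_flat_with_correct_power(self):
        rng = np.random.default_rng(1)
        sigma2 = 4.0
        totals, flatness = [], []
        for _ in range(100):
            x = rng.normal(0, np.sqrt(sigma2), int(30 * FS))
            freqs, psd = welch_psd(x, FS)
            df = freqs[1] - freqs[0]
            totals.append(psd[0].sum() * df)
            inner = psd[0][(freqs > 10) & (freqs < 115)]
            flatness.append(inner.max() / inner.min())
        assert np.mean(totals) == pytest.approx(sigma2, rel=0.02)
        assert np.median(flatness) < 3.0  # no systematic spectral shape

    def test_zero_signal_gives_zero_spectrum(self):
        _, psd = welch_psd(np.zeros((2, int(30 * FS))), FS)
        assert np.all(psd == 0)

    def test_segment_longer_than_window_rejected(self):
        with pytest.raises(SpectralError):
            welch_psd(np.zeros(100), FS, seg_s=1.0)


class TestBandPower:
    def test_constant_log_power_returns_magnitude(self):
        freqs = np.arange(0, 21.0)
        c = -2.5
        psd = np.full((1, len(freqs)), np.exp(c))
        band = BandDef("b", 9.5, 11.5)
        assert band_power(freqs, psd, band)[0] == pytest.approx(abs(c))

    def test_single_bin_band(self):
        freqs = np.arange(0, 21.0)
        psd = np.full((1, len(freqs)), 0.2)
        out = band_power(freqs, psd, BandDef("one", 9.5, 10.5))
        assert out[0] == pytest.approx(abs(np.log(0.2)))

    def test_rms_of_log_values(self):
        """Bins with log powers {1, 2, 2, 1} give sqrt(10/4)."""
        freqs = np.array([10.0, 11.0, 12.0, 13.0])
        psd = np.exp(np.array([[1.0, 2.0, 2.0, 1.0]]))
        out = band_power(freqs, psd, BandDef("b", 9.5, 13.5))
        assert out[0] == pytest.approx(np.sqrt(10 / 4))

    def test_nonpositive_bin_without_floor_is_error(self):
        freqs = np.arange(0, 5.0)
        psd = np.array([[1.0, 0.0, 1.0, 1.0, 1.0]])
        with pytest.raises(SpectralError):
            band_power(freqs, psd, BandDef("b", 0.5, 4.0), floor=None)

    def test_channel_order_invariance(self):
        rng = np.random.default_rng(2)
        freqs = np.arange(0, 30.0)
        psd = rng.uniform(0.5, 2.0, size=(4, 30))
        band = BandDef("b", 5.0, 15.0)
        out = band_power(freqs, psd, band)
        np.testing.assert_allclose(band_power(freqs, psd[::-1], band),
                                   out[::-1])


class TestBandDifference:
    def _table(self):
        rows = []
        for w in range(3):
            rows.append(("P1", "E1", "alpha", 0, w, 2.0, "NC", "NDE", "PE",
                         50.0, 5))
            rows.append(("P1", "E1", "theta", 0, w, 1.2, "NC", "NDE", "PE",
                         50.0, 5))
        return pd.DataFrame(rows, columns=[
            "participant", "channel", "band", "block", "window_index",
            "power", "state", "memory", "phase", "age", "shss"])

    def test_subtraction_and_naming(self):
        out = band_difference(self._table(), "alpha", "theta")
        assert (out["band"] == "specific_alpha").all()
        assert np.allclose(out["power"], 0.8)

    def test_identical_bands_give_zero(self):
        t = self._table()
        t.loc[t.band == "theta", "power"] = 2.0
        assert np.allclose(band_difference(t, "alpha", "theta")["power"], 0)

    def test_antisymmetry(self):
        t = self._table()
        ab = band_difference(t, "alpha", "theta")["power"].to_numpy()
        ba = band_difference(t, "theta", "alpha")["power"].to_numpy()
        np.testing.assert_allclose(ab, -ba)

    def test_mismatched_keys_rejected(self):
        t = self._table().iloc[:-1]  # drop one theta row
        with pytest.raises(SpectralError):
            band_difference(t, "alpha", "theta")


class TestProposeBands:
    freqs = np.arange(0.0, 31.0)

    def _one_over_f(self):
        f = np.maximum(self.freqs, 0.5)
        return 10.0 / f

    def _bump(self, centre, height=1.0, width=1.0):
        return np.exp(height * np.exp(-0.5 * ((self.freqs - centre) / width) ** 2))

    def test_pure_background_proposes_nothing(self):
        psd = self._one_over_f()
        assert propose_bands(self.freqs, {"frontal": psd, "central": psd,
                                          "posterior": psd}) == []

    def test_alpha_bump_is_found(self):
        psd = self._one_over_f() * self._bump(10.0)
        bands = propose_bands(self.freqs, {"frontal": psd, "central": psd,
                                           "posterior": psd})
        assert len(bands) >= 1
        assert any(b.lo <= 10.0 <= b.hi for b in bands)

    def test_three_bumps_give_three_disjoint_bands(self):
        psd = (self._one_over_f() * self._bump(2.0) * self._bump(10.0)
               * self._bump(18.0))
        bands = propose_bands(self.freqs, {"frontal": psd, "central": psd,
                                           "posterior": psd})
        assert len(bands) == 3
        for a, b in zip(bands, bands[1:]):
            assert a.hi < b.lo  # disjoint, ordered

    def test_nonpositive_spectrum_rejected(self):
        bad = self._one_over_f()
        bad[5] = 0.0
        with pytest.raises(SpectralError):
            propose_bands(self.freqs, {"frontal": bad})
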