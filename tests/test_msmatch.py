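import numpy as np
import pandas as pd
import pytest

from cyclomine.masscalc import PROTON, MatureCandidate, mz_for_charge
from cyclomine.msmatch import (
    ISOTOPE_DELTA,
    MatchParams,
    abundance_level,
    charge_from_spacing,
    confirm_alkylation,
    deconvolute,
    detect_envelopes,
    match_predicted,
)
from cyclomine.synthetic import build_transcriptome, simulate_peaklist


def _envelope_rows(M, z, rt, n=5, base=500.0, decay=0.8):
    mono = mz_for_charge(M, z)
    return [
        {"rt_min": rt, "mz": mono + k * ISOTOPE_DELTA / z, "intensity": base * decay**k}
        for k in range(n)
    ]


def _cand(mass, pid="p1", off=0):
    return MatureCandidate(
        precursor_id=pid, cd_index=0, start_offset=off, residues="G",
        topology="cyclic", n_cys=6, n_disulfide=3, calc_mass=mass,
    )


class TestChargeFromSpacing:
    def test_published_spacings(self):
        assert charge_from_spacing(0.502) == 2
        assert charge_from_spacing(0.334) == 3

    def test_singly_charged_not_assigned(self):
        assert charge_from_spacing(1.003) is None

    def test_residual_outside_tolerance(self):
        assert charge_from_spacing(0.58) is None

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            charge_from_spacing(0.0)


class TestDetectEnvelopes:
    def test_clean_triple_charge_envelope(self):
        M = 3100.0
        df = pd.DataFrame(_envelope_rows(M, 3, rt=10.0))
        (env,) = detect_envelopes(df)
        assert env.charge == 3
        assert env.mono_mz == pytest.approx(mz_for_charge(M, 3), abs=1e-9)
        assert len(env.peaks) == 5

    def test_interleaved_charge_states_both_recovered(self):
        df = pd.DataFrame(
            _envelope_rows(3100.0, 3, rt=10.0) + _envelope_rows(3138.4, 2, rt=10.0)
        ).sort_values("mz")
        envs = detect_envelopes(df)
        assert sorted(e.charge for e in envs) == [2, 3]
        for e in envs:
            M = e.charge * e.mono_mz - e.charge * PROTON
            assert M == pytest.approx(3100.0 if e.charge == 3 else 3138.4, abs=1e-6)

    def test_too_few_peaks_no_envelope(self):
        df = pd.DataFrame(
            [
                {"rt_min": 5.0, "mz": 1200.0, "intensity": 10.0},
                {"rt_min": 5.0, "mz": 1300.0, "intensity": 12.0},
            ]
        )
        assert detect_envelopes(df) == []

    def test_mz_window_applied(self):
        df = pd.DataFrame(_envelope_rows(2890.0, 3, rt=8.0))  # 3+ at ~964 m/z
        assert detect_envelopes(df) == []


class TestDeconvolute:
    def test_published_neutral_mass(self):
        df = pd.DataFrame(_envelope_rows(3138.37, 3, rt=12.0))
        (obs,) = deconvolute(detect_envelopes(df))
        assert obs.M == pytest.approx(3138.4, abs=0.1)

    def test_outside_neutral_window_dropped(self):
        df = pd.DataFrame(_envelope_rows(2500.0, 2, rt=12.0))
        assert deconvolute(detect_envelopes(df)) == []

    def test_two_charge_states_merge_to_one_observation(self):
        df = pd.DataFrame(
            _envelope_rows(3138.4, 3, rt=12.0, base=900)
            + _envelope_rows(3138.4, 2, rt=12.0, base=400)
        ).sort_values("mz")
        (obs,) = deconvolute(detect_envelopes(df))
        assert len(obs.envelopes) == 2
        assert obs.SI == pytest.approx(sum(900 * 0.8**k for k in range(5)))

    def test_two_plus_only_flagged_si_zero(self):
        df = pd.DataFrame(_envelope_rows(2890.14, 2, rt=9.0))
        (obs,) = deconvolute(detect_envelopes(df))
        assert obs.SI == 0.0
        assert "no_3plus_support" in obs.flags


class TestConfirmAlkylation:
    def _obs(self, M):
        df = pd.DataFrame(_envelope_rows(M, 2, rt=5.0))
        return deconvolute(detect_envelopes(df), apply_neutral_window=False)

    def test_published_pair_confirmed_at_default_tolerance(self):
        # observed 3138.3 native vs 3486.9 alkylated: delta 348.6, accepted
        # with the widened alkylation tolerance
        native = self._obs(3138.3)
        alk = self._obs(3486.9)
        (out,) = confirm_alkylation(native, alk)
        assert out.alkylation_confirmed == "yes"

    def test_strict_tolerance_would_reject_that_pair(self):
        params = MatchParams(alk_tol=0.40)
        (out,) = confirm_alkylation(self._obs(3138.3), self._obs(3486.9), params)
        assert out.alkylation_confirmed == "no"

    def test_no_partner_is_no(self):
        (out,) = confirm_alkylation(self._obs(3000.0), [])
        assert out.alkylation_confirmed == "no"

    def test_no_alkylated_run_is_untested(self):
        (out,) = confirm_alkylation(self._obs(3000.0), None)
        assert out.alkylation_confirmed == "untested"


class TestMatchPredicted:
    def _obs(self, M):
        df = pd.DataFrame(_envelope_rows(M, 3, rt=5.0))
        return deconvolute(detect_envelopes(df))

    def test_within_tolerance_match_with_delta(self):
        obs = self._obs(3138.30)
        df = match_predicted([_cand(3138.37)], obs)
        assert len(df) == 1
        assert df["delta"].iloc[0] == pytest.approx(0.07, abs=0.01)

    def test_exact_tolerance_boundary_rejected(self):
        obs = self._obs(3000.0)
        M = obs[0].M
        df = match_predicted([_cand(M + 0.40)], obs)
        assert len(df) == 0

    def test_many_to_many_with_single_best(self):
        obs = self._obs(3138.3)
        df = match_predicted([_cand(3138.25, "a"), _cand(3138.45, "b")], obs)
        assert len(df) == 2
        assert df["best"].sum() == 1
        assert df[df["best"]]["precursor_id"].iloc[0] == "a"

    def test_symmetric_in_sign(self):
        obs = self._obs(3138.3)
        M = obs[0].M
        up = match_predicted([_cand(M + 0.2)], obs)
        down = match_predicted([_cand(M - 0.2)], obs)
        assert len(up) == len(down) == 1


class TestAbundanceLevel:
    @pytest.mark.parametrize(
        "si,expected",
        [(100, "low"), (1500, "high"), (250, "medium"), (1000, "medium"), (600, "medium")],
    )
    def test_bins(self, si, expected):
        assert abundance_level(si) == expected

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            abundance_level(-1)


class TestRoundTrip:
    def test_zero_jitter_recovers_exact_masses(self):
        _, _, truth = build_transcriptome(n_per_species=1, n_decoys=0, rng_seed=5)
        peaks = simulate_peaklist(truth, jitter_sd=0.0)
        obs = deconvolute(detect_envelopes(peaks))
        true_masses = {round(cd.mass, 6) for p in truth.precursors for cd in p.cds}
        recovered = [o.M for o in obs]
        for m in true_masses:
            assert any(abs(m - r) < 1e-6 for r in recovered), m

    def test_abundance_tier_recovered_for_heavy_peptides(self):
        # peptides above ~2997 Da keep their 3+ envelope inside the m/z
        # window, so the tier survives the round trip
        _, _, truth = build_transcriptome(n_per_species=1, n_decoys=0, rng_seed=5)
        peaks = simulate_peaklist(truth, jitter_sd=0.0)
        obs = deconvolute(detect_envelopes(peaks))
        tiers = {}
        for p in truth.precursors:
            for cd in p.cds:
                if mz_for_charge(cd.mass, 3) >= 1000.0:
                    tiers.setdefault(round(cd.mass, 4), set()).add(p.tier)
        for o in obs:
            key = round(o.M, 4)
            if key in tiers and len(tiers[key]) == 1:
                assert o.abundance in tiers[key]
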