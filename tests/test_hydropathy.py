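"""Window profiles, SSD correspondence, HC score, hydrophobic moments."""
import cmath
import itertools
import math

import numpy as np
import pytest

from gpcrsel import (
    HelixCorrespondence,
    HydrophobicityScale,
    RegistryError,
    TetheredHelixAlignment,
    hc_score,
    helix_correspondence,
    hydrophobic_moment,
    profile_for_correspondence,
    tether_all,
    window_profile,
)
from gpcrsel.registry import STANDARD_RESIDUES

from conftest import random_protein


def brute_profile(seq, scale, window):
    """Independent windowed-mean oracle (truncated edge windows)."""
    half = (window - 1) // 2
    out = []
    for n in range(len(seq)):
        lo, hi = max(0, n - half), min(len(seq) - 1, n + half)
        vals = [scale[c] for c in seq[lo:hi + 1]]
        out.append(sum(vals) / len(vals))
    return out


def brute_moment(seq, scale, delta_deg=100.0, phase_deg=0.0):
    """Independent vector-sum oracle for one window."""
    vec = sum(
        scale[r] * cmath.exp(1j * math.radians(j * delta_deg + phase_deg))
        for j, r in enumerate(seq)
    )
    return abs(vec) / len(seq)


class TestWindowProfile:
    def test_constant_sequence_is_flat(self, scale):
        prof = window_profile("I" * 30, scale)
        assert np.allclose(prof.H, scale["I"])

    def test_window_one_is_raw_scale(self, scale):
        seq = "ARNDCQEGHILKMFPSTWYV"
        prof = window_profile(seq, scale, window=1)
        assert np.allclose(prof.H, [scale[c] for c in seq])

    def test_matches_brute_force_oracle(self, scale):
        rng = np.random.default_rng(11)
        for _ in range(25):
            seq = random_protein(rng, int(rng.integers(11, 41)))
            prof = window_profile(seq, scale)
            assert np.allclose(prof.H, brute_profile(seq, scale, 11),
                               atol=1e-9)

    def test_values_within_scale_range(self, scale):
        rng = np.random.default_rng(12)
        seq = random_protein(rng, 60)
        prof = window_profile(seq, scale)
        assert prof.H.min() >= scale.min - 1e-12
        assert prof.H.max() <= scale.max + 1e-12

    def test_input_validation(self, scale):
        with pytest.raises(RegistryError):
            window_profile("", scale)
        with pytest.raises(RegistryError):
            window_profile("ACDE", scale, window=4)
        with pytest.raises(RegistryError):
            window_profile("ACD", scale, window=11)

    def test_truncate_mode_ignores_flanks(self, fixture_registry, scale):
        q = fixture_registry.query
        lut = profile_for_correspondence(q, scale, edge_mode="truncate")
        s, e, _ = q.tm.span(1)
        sub = q.sequence[s - 1:e]
        assert lut[s] == pytest.approx(brute_profile(sub, scale, 11)[0])
        # extend mode uses genuine flanking residues instead
        lut_ext = profile_for_correspondence(q, scale, edge_mode="extend")
        full = brute_profile(q.sequence, scale, 11)
        assert lut_ext[s] == pytest.approx(full[s - 1])


def make_pair(n, helix_index=1):
    return TetheredHelixAlignment(
        helix_index=helix_index,
        pairs=tuple((i, 100 + i) for i in range(1, n + 1)),
        target_left_overhang=0, target_right_overhang=0,
        template_left_overhang=0, template_right_overhang=0,
    )


class TestHelixCorrespondence:
    def test_identity_is_zero_and_good(self):
        pair = make_pair(25)
        prof_t = {i: 0.5 for i in range(1, 26)}
        prof_p = {100 + i: 0.5 for i in range(1, 26)}
        hc = helix_correspondence(pair, prof_t, prof_p)
        assert hc.ssd == 0.0 and hc.s_i == 2

    @pytest.mark.parametrize("dh,n,ssd,spr,s_i", [
        (0.1, 25, 0.25, 0.01, 2),
        (0.4, 25, 4.0, 0.16, -1),
        (0.5, 4, 1.0, 0.25, -1),
    ])
    def test_arithmetic(self, dh, n, ssd, spr, s_i):
        pair = make_pair(n)
        prof_t = {i: 0.0 for i in range(1, n + 1)}
        prof_p = {100 + i: dh for i in range(1, n + 1)}
        hc = helix_correspondence(pair, prof_t, prof_p)
        assert hc.ssd == pytest.approx(ssd, abs=1e-9)
        assert hc.ssd_per_residue == pytest.approx(spr, abs=1e-9)
        assert hc.s_i == s_i

    def test_boundary_spr_exactly_0p1_scores_plus_two(self):
        # 2 paired positions with dH = 0.5 and a target helix of 5 residues:
        # ssd = 0.5 exactly, divisor 'target' -> spr = 0.5/5 = 0.1
        pair = TetheredHelixAlignment(
            helix_index=1, pairs=((1, 101), (2, 102)),
            target_left_overhang=1, target_right_overhang=2,
            template_left_overhang=0, template_right_overhang=0,
        )
        prof_t = {1: 0.0, 2: 0.0}
        prof_p = {101: 0.5, 102: 0.5}
        hc = helix_correspondence(pair, prof_t, prof_p, divisor="target")
        assert hc.ssd_per_residue == 0.1
        assert hc.s_i == 2

    def test_symmetry_and_divisors(self):
        pair = make_pair(10)
        prof_t = {i: 0.1 * i for i in range(1, 11)}
        prof_p = {100 + i: 0.05 * i for i in range(1, 11)}
        fwd = helix_correspondence(pair, prof_t, prof_p)
        swapped = TetheredHelixAlignment(
            helix_index=1, pairs=tuple((j, i) for i, j in pair.pairs),
            target_left_overhang=0, target_right_overhang=0,
            template_left_overhang=0, template_right_overhang=0,
        )
        rev = helix_correspondence(swapped, prof_p, prof_t)
        assert rev.ssd == pytest.approx(fwd.ssd)

    def test_scale_shift_leaves_ssd_invariant(self, fixture_registry, scale):
        q = fixture_registry.query
        t = fixture_registry.records[1].receptor
        shifted = HydrophobicityScale(
            name="shifted",
            values={k: v + 0.3 for k, v in scale.values.items()},
        )
        for sc_a, sc_b in [(scale, shifted)]:
            ssd_a, ssd_b = [], []
            for use in (sc_a, sc_b):
                qp = profile_for_correspondence(q, use)
                tp = profile_for_correspondence(t, use)
                ssd = [
                    helix_correspondence(ha, qp, tp).ssd
                    for ha in tether_all(q, t)
                ]
                (ssd_a if use is sc_a else ssd_b).extend(ssd)
            assert ssd_a == pytest.approx(ssd_b, abs=1e-9)


class TestHCScore:
    def test_enumerated_outcome_set(self):
        observed = set()
        for combo in itertools.product((2, -1), repeat=7):
            helices = [
                HelixCorrespondence(helix_index=k + 1, n_paired=20,
                                    ssd=1.0, ssd_per_residue=0.05, s_i=s)
                for k, s in enumerate(combo)
            ]
            observed.add(hc_score(helices))
        assert observed == {-7, -4, -1, 2, 5, 8, 11, 14}

    def test_requires_seven(self):
        with pytest.raises(RegistryError):
            hc_score([])


class TestHydrophobicMoment:
    def test_null_scale_gives_zero(self):
        zero = HydrophobicityScale(
            name="zero", values={r: 0.0 for r in STANDARD_RESIDUES}
        )
        m = hydrophobic_moment("ILVFMILVFMI", zero)
        assert m.mu_max == pytest.approx(0.0)

    def test_single_residue_is_abs_value(self, scale):
        m = hydrophobic_moment("R", scale)
        assert m.mu_max == pytest.approx(abs(scale["R"]))

    def test_matches_brute_force_on_11mers(self, scale):
        rng = np.random.default_rng(21)
        for _ in range(25):
            seq = random_protein(rng, 11)
            m = hydrophobic_moment(seq, scale)
            assert m.mu_max == pytest.approx(brute_moment(seq, scale),
                                             abs=1e-9)

    def test_sliding_window_takes_maximum(self, scale):
        rng = np.random.default_rng(22)
        seq = random_protein(rng, 30)
        m = hydrophobic_moment(seq, scale)
        expected = max(
            brute_moment(seq[i:i + 11], scale) for i in range(20)
        )
        assert m.mu_max == pytest.approx(expected, abs=1e-9)

    def test_magnitude_invariant_under_global_rotation(self, scale):
        rng = np.random.default_rng(23)
        seq = random_protein(rng, 11)
        m = hydrophobic_moment(seq, scale)
        for phase in (33.0, 77.0, 180.0):
            assert brute_moment(seq, scale, phase_deg=phase) == pytest.approx(
                m.mu_max, abs=1e-9
            )

    def test_wheel_angles(self, scale):
        m = hydrophobic_moment("ACDE", scale)
        angles = [a for _, a, _ in m.wheel]
        assert angles == [0.0, 100.0, 200.0, 300.0]
        assert all(0 <= a < 360 for a in angles)
        m5 = hydrophobic_moment("ACDEF", scale)
        assert [a for _, a, _ in m5.wheel][4] == pytest.approx(40.0)
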