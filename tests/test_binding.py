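"""Binding simulation: string-vector encoding, association constants,
Langmuir signals, noise and normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aawsim as aw
from aawsim.binding import BindingProfile, ThermoParams


def brute_force_signal(lib, mix, h, theta):
    """Independent step-by-step evaluation of the full formula chain
    (encode -> dot -> exp -> Langmuir), pure-python loops only."""
    out = []
    for _, seq in lib:
        p = [h[aw.ALPHABET.index(ch)] for ch in seq]
        load = 0.0
        for k in range(mix.n_ab):
            y = sum(mix.A[k][j] * p[j] for j in range(len(p)))
            K = math.exp((theta.beta0 + theta.beta1 * y) / (theta.R * theta.T))
            load += mix.c[k] * K
        out.append(load / (1.0 + load))
    return np.array(out)


class TestAssignedWeights:
    def test_deterministic_and_bounded(self):
        h = aw.sample_assigned_aaws(seed=5)
        assert np.array_equal(h, aw.sample_assigned_aaws(seed=5))
        assert h.shape == (20,) and np.all((h >= 0) & (h <= 1))

    def test_uniform_moment(self):
        pooled = np.concatenate([aw.sample_assigned_aaws(s) for s in range(500)])
        assert pooled.size == 10_000
        assert abs(pooled.mean() - 0.5) < 0.02


class TestEncoding:
    def test_lookup(self):
        h = np.zeros(20)
        h[aw.ALPHABET.index("A")] = 0.2
        h[aw.ALPHABET.index("C")] = 0.9
        assert np.allclose(aw.encode_peptide("AC", h), [0.2, 0.9])

    def test_positional(self, assigned_h):
        p = aw.encode_peptide("ACDEF", assigned_h)
        q = aw.encode_peptide("FEDCA", assigned_h)
        assert np.allclose(p, q[::-1]) and not np.allclose(p, q)

    def test_unknown_residue(self, assigned_h):
        with pytest.raises(ValueError, match="X"):
            aw.encode_peptide("AXC", assigned_h)


class TestAntibody:
    @settings(max_examples=30, deadline=None)
    @given(l=st.integers(1, 40), seed=st.integers(0, 10_000))
    def test_unit_norm_property(self, l, seed):
        a = aw.sample_antibody(l, seed)
        assert a.shape == (l,)
        assert abs(np.linalg.norm(a) - 1.0) < 1e-12

    def test_l1_is_sign(self):
        assert aw.sample_antibody(1, 3)[0] in (-1.0, 1.0)

    def test_symmetric_signs(self):
        draws = np.concatenate([aw.sample_antibody(14, s) for s in range(500)])
        assert 0.45 < (draws < 0).mean() < 0.55


class TestAssociation:
    def test_dot_product(self):
        assert aw.binding_association([1.0, 0.0], [0.2, 0.9]) == pytest.approx(0.2)
        assert aw.binding_association([0.0, 1.0], [0.5, 0.0]) == 0.0

    def test_cauchy_schwarz_bound(self, assigned_h):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = aw.sample_antibody(14, rng)
            seq = "".join(rng.choice(list(aw.ALPHABET), 14))
            y = aw.binding_association(a, aw.encode_peptide(seq, assigned_h))
            assert abs(y) <= math.sqrt(14)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            aw.binding_association([1.0], [1.0, 2.0])


class TestAssociationConstant:
    def test_closed_forms(self):
        theta = ThermoParams()
        assert aw.association_constant(0.0, theta) == pytest.approx(1.0)
        assert aw.association_constant(1.0, theta) == pytest.approx(math.e)
        rt = theta.R * theta.T
        flat = ThermoParams(beta0=rt * math.log(2), beta1=0.0)
        assert aw.association_constant(123.4, flat) == pytest.approx(2.0)

    def test_overflow_guard(self):
        with pytest.raises(OverflowError):
            aw.association_constant(1e6, ThermoParams())


class TestLangmuirSignal:
    def test_single_antibody_half_occupancy(self):
        # h = 0 makes every association 0, so K = 1 and S = 1/(1+1)
        lib = aw.PeptideLibrary(ids=("p1", "p2"), sequences=("ACD", "WYA"))
        mix = aw.make_mixture(1, 3, seed=0)
        S = aw.simulate_signal(lib, mix, np.zeros(20))
        assert np.allclose(S.values, 0.5, atol=1e-15)

    def test_single_antibody_closed_form(self, tiny_library, assigned_h):
        mix = aw.make_mixture(1, 3, seed=4)
        S = aw.simulate_signal(tiny_library, mix, assigned_h)
        P = np.vstack(
            [aw.encode_peptide(seq, assigned_h) for _, seq in tiny_library]
        )
        K = np.exp(P @ mix.A[0])
        assert np.allclose(S.values, K / (1 + K), atol=1e-12)

    def test_two_antibody_arithmetic(self):
        # crafted unit antibodies and h give K = (1, 3):
        # S = (0.5*1 + 0.5*3) / (1 + 0.5*1 + 0.5*3) = 2/3
        lib = aw.PeptideLibrary(ids=("p1",), sequences=("AC",))
        w = math.log(3.0) / math.sqrt(2.0)  # ~0.777, a valid weight in [0, 1]
        h = np.zeros(20)
        h[aw.ALPHABET.index("A")] = w
        h[aw.ALPHABET.index("C")] = w
        r = 1.0 / math.sqrt(2.0)
        mix = aw.AntibodyMixture(
            A=np.array([[r, -r], [r, r]]), c=np.array([0.5, 0.5])
        )  # y = (0, ln 3) against p = (w, w)
        S = aw.simulate_signal(lib, mix, h)
        assert S.values[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_saturation_limit(self, tiny_library):
        # K = 1e6 for every pair drives occupancy to 1
        rt = ThermoParams().R * ThermoParams().T
        theta = ThermoParams(beta0=rt * math.log(1e6), beta1=0.0)
        mix = aw.make_mixture(2, 3, seed=1)
        S = aw.simulate_signal(tiny_library, mix, np.zeros(20), theta)
        assert np.all(S.values > 0.9999) and np.all(S.values < 1.0)

    def test_brute_force_oracle(self):
        # full-chain agreement on tiny instances
        rng = np.random.default_rng(9)
        for seed in range(3):
            lib = aw.generate_library(5, 3, seed=seed)
            h = aw.sample_assigned_aaws(seed)
            mix = aw.make_mixture(3, 3, seed=seed + 100)
            S = aw.simulate_signal(lib, mix, h)
            assert np.allclose(
                S.values, brute_force_signal(lib, mix, h, ThermoParams()),
                atol=1e-12, rtol=0,
            )

    def test_dimension_mismatch(self, tiny_library, assigned_h):
        mix = aw.make_mixture(2, 5, seed=0)
        with pytest.raises(ValueError):
            aw.simulate_signal(tiny_library, mix, assigned_h)

    def test_position_dependence_witness(self, assigned_h):
        # composition-identical peptides with different order give different
        # signals for a single antibody -- the asymmetry composition-only
        # regression cannot represent
        lib = aw.PeptideLibrary(ids=("p1", "p2"), sequences=("ACDEF", "FEDCA"))
        mix = aw.make_mixture(1, 5, seed=2)
        S = aw.simulate_signal(lib, mix, assigned_h)
        assert abs(S.values[0] - S.values[1]) > 1e-6


class TestMixture:
    def test_uniform_simplex(self):
        mix = aw.make_mixture(4, 3, seed=0)
        assert np.allclose(mix.c, 0.25)
        assert np.allclose(np.linalg.norm(mix.A, axis=1), 1.0)

    def test_dominance_renormalization(self):
        mix = aw.make_mixture(2, 3, seed=0, dominance_factor=3.0)
        assert np.allclose(mix.c, [0.75, 0.25])
        assert mix.c.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dominance_16000_by_1000(self):
        mix = aw.make_mixture(16000, 3, seed=0, dominance_factor=1000.0)
        # renormalization rule: 1000 / (1000 + 15999)
        assert mix.c[0] == pytest.approx(1000.0 / 16999.0, abs=1e-12)
        assert np.allclose(mix.c[1:], 1.0 / 16999.0)
        assert mix.c.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fixed_dominant_vector(self):
        dom = aw.sample_antibody(3, seed=42)
        mix = aw.make_mixture(5, 3, seed=0, dominant=dom)
        assert np.allclose(mix.A[0], dom)

    def test_dominance_needs_two(self):
        with pytest.raises(ValueError):
            aw.make_mixture(1, 3, seed=0, dominance_factor=10.0)


class TestNoiseAndNormalization:
    def test_zero_sigma_identity(self, standard_library, assigned_h):
        mix = aw.make_mixture(10, 14, seed=0)
        S = aw.simulate_signal(standard_library, mix, assigned_h)
        assert aw.apply_noise(S, 0.0, seed=1) is S

    def test_noise_moment_and_determinism(self):
        S = BindingProfile(values=np.full(100_000, 0.5), stage="raw_fraction")
        out = aw.apply_noise(S, 0.01, seed=3)
        rel = out.values / S.values - 1.0
        assert abs(rel.std() - 0.01) < 0.01 * 0.05
        assert np.array_equal(out.values, aw.apply_noise(S, 0.01, seed=3).values)
        assert np.all((out.values > 0) & (out.values < 1))

    def test_negative_sigma(self):
        S = BindingProfile(values=np.array([0.5]), stage="raw_fraction")
        with pytest.raises(ValueError):
            aw.apply_noise(S, -0.1, seed=0)

    def test_normalize_moments(self, standard_library, assigned_h):
        mix = aw.make_mixture(20, 14, seed=5)
        S = aw.simulate_signal(standard_library, mix, assigned_h)
        norm = aw.normalize_signal(S)
        assert abs(norm.values.mean()) < 1e-9
        assert abs(norm.values.std(ddof=1) - 1.0) < 1e-9

    def test_normalize_constant_rejected(self):
        S = BindingProfile(values=np.full(10, 0.3), stage="raw_fraction")
        with pytest.raises(ValueError, match="degenerate"):
            aw.normalize_signal(S)

    def test_normalize_idempotent_up_to_affine(self, standard_library, assigned_h):
        mix = aw.make_mixture(20, 14, seed=5)
        S = aw.simulate_signal(standard_library, mix, assigned_h)
        once = aw.normalize_signal(S)
        # exp-invert (with an offset keeping values in (0,1)), renormalize:
        # the same normalized vector comes back
        twice = aw.normalize_signal(
            BindingProfile(values=np.exp(once.values - 10), stage="raw_fraction")
        )
        assert np.allclose(twice.values, once.values, atol=1e-9)

    def test_raw_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            BindingProfile(values=np.array([0.0, 0.5]), stage="raw_fraction")
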