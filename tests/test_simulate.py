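import numpy as np
import pytest

from gecon.containers import ExpressionMatrix
from gecon.errors import ParameterError
from gecon.network import build_network
from gecon.simulate import (PatternSpec, derive_member, generate_dataset,
                            make_base_profile)
from gecon.support import build_correlogram
from gecon.transform import transform_matrix


def _recover(ds, tau=20.0, theta=0.5):
    """Run the full reconstruction and return predicted {pair: sign}."""
    net = build_network(build_correlogram(transform_matrix(ds.matrix), tau),
                        theta)
    return {tuple(sorted((a, b))): s for a, b, s, _ in net.iter_edges()}


class TestBaseProfile:
    def test_deterministic_given_seed(self):
        a = make_base_profile(10, np.random.default_rng(4))
        b = make_base_profile(10, np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_length_and_nondegenerate_steps(self):
        p = make_base_profile(3, np.random.default_rng(0))
        assert p.shape == (3,)
        for seed in range(10):
            p = make_base_profile(20, np.random.default_rng(seed))
            assert np.all(np.abs(np.diff(p)) > 0)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ParameterError):
            make_base_profile(2, np.random.default_rng(0))


class TestDeriveMember:
    @pytest.fixture
    def base(self):
        return make_base_profile(12, np.random.default_rng(1), level=600.0)

    def _regs(self, profile):
        em = ExpressionMatrix(["g"], [f"c{t}" for t in range(len(profile))],
                              profile[None, :])
        return transform_matrix(em).regulations[0]

    def test_shifted_is_exact_offset_with_same_regulations(self, base):
        member = derive_member(base, "shifted", 5.0, 1.0, 0.0,
                               np.random.default_rng(0))
        assert np.allclose(member, base + 5.0)
        assert np.array_equal(self._regs(member), self._regs(base))

    def test_scaled_is_exact_multiple_with_identical_angles(self, base):
        member = derive_member(base, "scaled", 0.0, 3.0, 0.0,
                               np.random.default_rng(0))
        assert np.allclose(member, base * 3.0)
        em = lambda p: transform_matrix(ExpressionMatrix(
            ["g"], [f"c{t}" for t in range(len(p))], p[None, :]))
        assert np.allclose(em(member).angles, em(base).angles)

    def test_inverted_flips_every_regulation(self, base):
        member = derive_member(base, "inverted", 0.0, 1.0, 0.0,
                               np.random.default_rng(0))
        assert np.array_equal(self._regs(member), -self._regs(base))

    def test_mixed_flips_some_but_not_all(self, base):
        member = derive_member(base, "mixed", 0.0, 1.0, 0.0,
                               np.random.default_rng(12))
        agree = self._regs(member) == self._regs(base)
        assert agree.any() and not agree.all()

    def test_unknown_kind_rejected(self, base):
        with pytest.raises(ParameterError):
            derive_member(base, "sideways", 0.0, 1.0, 0.0,
                          np.random.default_rng(0))


class TestGenerateDataset:
    def test_same_seed_identical_dataset(self):
        a = generate_dataset(PatternSpec(seed=5))
        b = generate_dataset(PatternSpec(seed=5))
        assert np.array_equal(a.matrix.values, b.matrix.values)
        assert a.truth_network.positives == b.truth_network.positives
        assert a.truth_signs == b.truth_signs

    def test_truth_is_within_module_clique(self):
        ds = generate_dataset(PatternSpec(seed=2))
        expected = set()
        for module in ds.module_labels:
            for x in range(len(module)):
                for y in range(x + 1, len(module)):
                    expected.add(tuple(sorted((module[x], module[y]))))
        assert ds.truth_network.positives == expected
        assert not any(g.startswith("BG") for p in expected for g in p)

    def test_inverted_module_signs_are_mixed_products(self):
        ds = generate_dataset(PatternSpec(seed=0))
        inverted_members = ds.module_labels[2]   # kinds default order
        base = inverted_members[0]
        for other in inverted_members[1:]:
            assert ds.truth_signs[tuple(sorted((base, other)))] == -1
        # two inverted members are mutually positively co-regulated
        pair = tuple(sorted((inverted_members[1], inverted_members[2])))
        assert ds.truth_signs[pair] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_zero_noise_scaled_modules_always_fully_recovered(self, seed):
        """Scaling preserves edge angles exactly, so noise-free scaled
        modules reach positive support 1 on every within-module pair and
        recall is structurally perfect (+1 signs throughout)."""
        spec = PatternSpec(n_modules=2, genes_per_module=6, n_conditions=12,
                           pattern_kinds=("scaled", "scaled"),
                           noise_sd=0.0, n_background_genes=0, seed=seed)
        ds = generate_dataset(spec)
        pred = _recover(ds)
        assert ds.truth_network.positives <= set(pred)
        assert all(pred[p] == 1 for p in ds.truth_network.positives)

    def test_zero_noise_exact_recovery_instance(self):
        """End-to-end regression anchor: for this seeded noise-free
        scaled+inverted instance the reconstruction returns exactly the
        planted network, signs included.  (Mirror matching of the inverted
        module is approximate by nature, so exactness is per-instance, not
        structural; the scaled part is covered structurally above.)"""
        spec = PatternSpec(n_modules=2, genes_per_module=6, n_conditions=12,
                           pattern_kinds=("scaled", "inverted"),
                           noise_sd=0.0, n_background_genes=5, seed=42)
        ds = generate_dataset(spec)
        pred = _recover(ds)
        assert set(pred) == ds.truth_network.positives
        assert all(pred[p] == s for p, s in ds.truth_signs.items())

    def test_background_only_yields_few_edges(self):
        spec = PatternSpec(n_modules=0, genes_per_module=10, n_conditions=15,
                           pattern_kinds=(), n_background_genes=30, seed=3)
        ds = generate_dataset(spec)
        pred = _recover(ds)
        assert len(pred) <= 5   # ~435 null pairs at chance level
        assert ds.truth_network.positives == set()

    def test_recovery_degrades_monotonically_with_noise(self):
        """Mean F1 of edge recovery is non-increasing across noise levels."""
        def mean_f1(noise_sd):
            f1s = []
            for seed in range(5):
                ds = generate_dataset(PatternSpec(seed=seed, noise_sd=noise_sd))
                pred = _recover(ds)
                truth = ds.truth_network.positives
                tp = len(set(pred) & truth)
                prec = tp / len(pred) if pred else 1.0
                rec = tp / len(truth)
                f1s.append(0.0 if tp == 0 else 2 * prec * rec / (prec + rec))
            return np.mean(f1s)

        scores = [mean_f1(nz) for nz in (5.0, 50.0, 150.0)]
        assert scores[0] >= scores[1] >= scores[2]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            PatternSpec(genes_per_module=1)
        with pytest.raises(ParameterError):
            PatternSpec(pattern_kinds=("shifted",))
        with pytest.raises(ParameterError):
            PatternSpec(noise_sd=-1.0)
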