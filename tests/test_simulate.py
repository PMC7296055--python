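"""Markov-chain genome simulator and amelioration scenarios."""

import filecmp

import numpy as np
import pytest

from plasmidhost.composition import kmer_strings, rho_vector
from plasmidhost.records import GenomeRecord
from plasmidhost.screen import predict_host_similarity
from plasmidhost.simulate import (
    MarkovModel,
    ameliorate,
    build_scenario,
    generate_sequence,
    make_markov_model,
)


class TestMakeMarkovModel:
    def test_deterministic_per_seed(self):
        a = make_markov_model(5, order=1, concentration=1.0)
        b = make_markov_model(5, order=1, concentration=1.0)
        assert np.array_equal(a.transitions, b.transitions)
        assert a.content_hash() == b.content_hash()

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_shapes_and_row_sums(self, order):
        m = make_markov_model(1, order=order)
        assert m.transitions.shape == (4**order, 4)
        assert np.allclose(m.transitions.sum(axis=1), 1, atol=1e-12)
        assert m.initial_distribution.sum() == pytest.approx(1, abs=1e-12)

    def test_large_concentration_approaches_uniform(self):
        m = make_markov_model(2, order=1, concentration=1e6)
        assert np.abs(m.transitions - 0.25).max() < 0.01

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            make_markov_model(1, order=3)
        with pytest.raises(ValueError):
            make_markov_model(1, concentration=0)


class TestGenerateSequence:
    def test_degenerate_chain_emits_single_base(self):
        trans = np.zeros((4, 4))
        trans[:, 0] = 1.0
        m = MarkovModel(order=1, initial_distribution=np.array([1.0, 0, 0, 0]),
                        transitions=trans)
        assert generate_sequence(m, 50, 1) == "A" * 50

    def test_length_and_alphabet(self):
        m = make_markov_model(3, order=2)
        seq = generate_sequence(m, 10, 4)
        assert len(seq) == 10 and set(seq) <= set("ACGT")
        with pytest.raises(ValueError):
            generate_sequence(m, 2, 4)

    def test_deterministic_per_seed(self):
        m = make_markov_model(6, order=1)
        assert generate_sequence(m, 1000, 9) == generate_sequence(m, 1000, 9)

    def test_empirical_transitions_converge(self):
        m = make_markov_model(7, order=1, concentration=2.0)
        seq = generate_sequence(m, 10**5, 8)
        codes = np.frombuffer(seq.encode(), np.uint8)
        lut = np.zeros(256, int)
        for i, b in enumerate("ACGT"):
            lut[ord(b)] = i
        c = lut[codes]
        counts = np.zeros((4, 4))
        np.add.at(counts, (c[:-1], c[1:]), 1)
        observed = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(observed - m.transitions).max() < 0.02

    def test_cg_avoidance_shows_in_rho(self):
        m = make_markov_model(10, order=1, concentration=5.0)
        trans = m.transitions.copy()
        trans[1] = [0.4, 0.3, 0.01, 0.29]  # strong CG avoidance: P(G|C)=0.01
        m = MarkovModel(order=1, initial_distribution=m.initial_distribution,
                        transitions=trans / trans.sum(axis=1, keepdims=True))
        seq = generate_sequence(m, 10**5, 11)
        v = rho_vector(seq, 2)
        assert v.values[kmer_strings(2).index("CG")] < 0.2


class TestAmeliorate:
    def test_endpoints(self):
        a = make_markov_model(1, order=1)
        b = make_markov_model(2, order=1)
        assert np.allclose(ameliorate(a, b, 0).transitions, a.transitions)
        assert np.allclose(ameliorate(a, b, 1).transitions, b.transitions)

    def test_convex_mixing(self):
        row_a = np.array([[1.0, 0, 0, 0]])
        row_b = np.array([[0, 1.0, 0, 0]])
        a = MarkovModel(order=0, initial_distribution=np.array([1.0]), transitions=row_a)
        b = MarkovModel(order=0, initial_distribution=np.array([1.0]), transitions=row_b)
        mixed = ameliorate(a, b, 0.5)
        assert mixed.transitions[0] == pytest.approx([0.5, 0.5, 0, 0])

    def test_order_mismatch(self):
        with pytest.raises(ValueError):
            ameliorate(make_markov_model(1, order=1), make_markov_model(1, order=2), 0.5)


class TestBuildScenario:
    def test_seed_reproducibility_byte_identical(self, tmp_path):
        kwargs = dict(n_transconjugant_hosts=2, n_other_hosts=2,
                      chrom_length=100_000, plasmid_length=10_000,
                      alpha=0.5, seed=13)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        build_scenario(**kwargs).write(d1)
        build_scenario(**kwargs).write(d2)
        for name in ("hosts.fasta", "plasmid.fasta", "metadata.tsv", "manifest.json"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_metadata_covers_hosts_with_truth_labels(self, small_bundle):
        accs = {r.id for r in small_bundle.host_records}
        assert set(small_bundle.metadata["accession"]) == accs
        groups = set(small_bundle.metadata["group"])
        assert groups == {"Transconjugants", "Others"}
        assert len(small_bundle.transconjugant_genera) == 3

    def test_argument_validation(self):
        with pytest.raises(ValueError, match="chrom_length"):
            build_scenario(chrom_length=50_000)
        with pytest.raises(ValueError, match="alpha"):
            build_scenario(alpha=1.5)

    def test_self_model_plasmid_scores_higher_than_unrelated(self):
        # a plasmid generated from a host's own chain looks like that host
        wins = 0
        for r in range(10):
            own = make_markov_model(20 * r + 1, order=2, concentration=2.0)
            other = make_markov_model(20 * r + 2, order=2, concentration=2.0)
            chrom_own = GenomeRecord(
                id="own", sequence=generate_sequence(own, 500_000, 20 * r + 3))
            chrom_other = GenomeRecord(
                id="oth", sequence=generate_sequence(other, 500_000, 20 * r + 4))
            plasmid = GenomeRecord(
                id="p", sequence=generate_sequence(own, 50_000, 20 * r + 5),
                role="plasmid")
            p_own = predict_host_similarity(plasmid, chrom_own, 2).empirical_p
            p_other = predict_host_similarity(plasmid, chrom_other, 2).empirical_p
            wins += p_own > p_other
        assert wins >= 9
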