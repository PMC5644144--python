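"""The Markov sequence generator: calibration, determinism, round trips."""

import numpy as np
import pytest
from scipy import stats as sps

from cpgoe.cpg import count_dinucleotides, cpg_oe
from cpgoe.sequence_io import extract_gene_bodies, write_fasta
from cpgoe.simulate import (
    A,
    C,
    G,
    T,
    ClassSpec,
    GenomeSimSpec,
    build_transition_matrix,
    collembolan_like_spec,
    depletion_for_target_oe,
    expected_cpg_oe,
    generate_annotated_genome,
    generate_gene_set,
    generate_sequence,
    honeybee_like_spec,
)


def spec_for(d, gc=0.4, **kwargs):
    return ClassSpec("test", 1.0, d, gc, **kwargs)


class TestTransitionMatrix:
    def test_no_depletion_at_gc_half_is_uniform(self):
        P, pi = build_transition_matrix(0.5, 1.0)
        np.testing.assert_allclose(P, 0.25, atol=1e-12)
        np.testing.assert_allclose(pi, 0.25, atol=1e-12)

    def test_rows_sum_to_one(self):
        for d in (0.1, 0.5, 1.0, 1.5):
            P, pi = build_transition_matrix(0.35, d)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(pi.sum(), 1.0, atol=1e-12)

    def test_depletion_bounds_enforced(self):
        with pytest.raises(ValueError):
            build_transition_matrix(0.5, 0.0)
        with pytest.raises(ValueError):
            build_transition_matrix(0.5, -0.5)
        with pytest.raises(ValueError):
            build_transition_matrix(0.5, 1.6)

    def test_expected_oe_matches_independent_stationary_oracle(self):
        # oracle: stationary distribution by matrix power, o/e from its
        # definition (CpG frequency over pi_C * pi_G), computed independently
        P, _ = build_transition_matrix(0.5, 0.5)
        pi_oracle = np.linalg.matrix_power(P.T, 200)[:, 0]
        oe_oracle = (pi_oracle[C] * P[C, G]) / (pi_oracle[C] * pi_oracle[G])
        assert expected_cpg_oe(0.5, 0.5) == pytest.approx(oe_oracle, abs=1e-10)

    def test_expected_oe_matches_long_run_simulation(self):
        rec = generate_sequence(200_000, spec_for(0.5, gc=0.5), seed=123)
        assert cpg_oe(rec).cpg_oe == pytest.approx(expected_cpg_oe(0.5, 0.5), abs=0.05)

    def test_expected_oe_strictly_increasing_in_depletion(self):
        grid = [0.1, 0.3, 0.5, 0.8, 1.0, 1.2, 1.5]
        oes = [expected_cpg_oe(0.35, d) for d in grid]
        assert all(a < b for a, b in zip(oes, oes[1:]))

    def test_target_inversion_round_trip(self):
        for target, gc in [(0.7, 0.3625), (0.79, 0.334), (0.35, 0.35)]:
            d = depletion_for_target_oe(target, gc)
            assert expected_cpg_oe(gc, d) == pytest.approx(target, abs=1e-9)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            depletion_for_target_oe(3.0, 0.35)


class TestGenerateSequence:
    def test_deterministic_given_seed(self):
        for length in (2, 500):
            a = generate_sequence(length, spec_for(0.5), seed=7)
            b = generate_sequence(length, spec_for(0.5), seed=7)
            assert a.residues == b.residues
        c = generate_sequence(500, spec_for(0.5), seed=8)
        assert b.residues != c.residues

    @pytest.mark.parametrize("d, seed", [(1.0, 10), (0.3, 3)])
    def test_empirical_oe_matches_analytic(self, d, seed):
        rec = generate_sequence(100_000, spec_for(d, gc=0.5), seed=seed)
        expected = expected_cpg_oe(0.5, d)
        assert cpg_oe(rec).cpg_oe == pytest.approx(expected, abs=0.05)

    def test_dinucleotide_frequencies_fit_the_chain(self):
        P, pi = build_transition_matrix(0.4, 0.5)
        rejected = 0
        for seed in range(8):
            rec = generate_sequence(50_000, spec_for(0.5, gc=0.4), seed=seed)
            counts = count_dinucleotides(rec)
            obs = np.array(
                [counts[b1 + b2] for b1 in "ACGT" for b2 in "ACGT"], dtype=float
            )
            exp_freq = (pi[:, None] * P).ravel()
            _, p = sps.chisquare(obs, exp_freq * obs.sum())
            rejected += p < 0.01
        assert rejected <= 1

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            generate_sequence(1, spec_for(0.5), seed=0)


class TestGenerateGeneSet:
    def test_single_class_truth_table(self):
        spec = GenomeSimSpec(classes=(spec_for(0.5),), n_genes=100, seed=1)
        records, truth = generate_gene_set(spec)
        assert len(records) == 100
        assert set(truth["class_label"]) == {"test"}
        assert list(truth["gene_id"]) == [r.id for r in records]

    def test_class_counts_within_binomial_bounds(self):
        spec = honeybee_like_spec(n_genes=2000, seed=5)
        _, truth = generate_gene_set(spec)
        n_methylated = (truth["class_label"] == "methylated").sum()
        half_width = 2.576 * np.sqrt(2000 * 0.25)  # 99% binomial bounds
        assert abs(n_methylated - 1000) <= half_width

    def test_lengths_respect_floor(self):
        spec = GenomeSimSpec(
            classes=(spec_for(0.5, length_mean=150, length_sd=400, length_min=100),),
            n_genes=200,
            seed=2,
        )
        records, truth = generate_gene_set(spec)
        assert min(len(r) for r in records) >= 100
        assert (truth["length"] == [len(r) for r in records]).all()

    def test_byte_identical_reproducibility(self, tmp_path):
        spec = collembolan_like_spec(n_genes=50, seed=11)
        outputs = []
        for run in ("a", "b"):
            records, truth = generate_gene_set(spec)
            fa = tmp_path / f"{run}.fa"
            tt = tmp_path / f"{run}.tsv"
            write_fasta(records, fa)
            truth.to_csv(tt, sep="\t", index=False)
            outputs.append((fa.read_bytes(), tt.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_mean_oe_increases_with_depletion(self):
        means = []
        for d in (0.2, 0.5, 0.8, 1.1):
            spec = GenomeSimSpec(
                classes=(spec_for(d, length_mean=3000, length_sd=200, length_min=500),),
                n_genes=60,
                seed=3,
            )
            records, _ = generate_gene_set(spec)
            means.append(np.mean([cpg_oe(r).cpg_oe for r in records]))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestAnnotatedGenome:
    def test_single_gene_round_trip(self):
        spec = GenomeSimSpec(
            classes=(spec_for(0.5, length_mean=300, length_sd=0, length_min=200),),
            n_genes=1,
            seed=4,
        )
        bundle = generate_annotated_genome(spec)
        (body,) = extract_gene_bodies(
            list(bundle.genome), list(bundle.genes), mode="spliced"
        )
        assert body.residues == bundle.gene_sequences[0].residues

    def test_many_genes_within_bounds_and_disjoint(self):
        spec = honeybee_like_spec(n_genes=200, seed=6)
        bundle = generate_annotated_genome(spec)
        lengths = {r.id: len(r) for r in bundle.genome}
        assert len(bundle.genome) == spec.scaffold_count
        by_scaffold: dict[str, list] = {}
        for gene in bundle.genes:
            assert 0 <= gene.span[0] < gene.span[1] <= lengths[gene.scaffold_id]
            by_scaffold.setdefault(gene.scaffold_id, []).append(gene.span)
        for spans in by_scaffold.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_spliced_extraction_reproduces_exonic_sequence_exactly(self):
        spec = honeybee_like_spec(n_genes=80, seed=7)
        bundle = generate_annotated_genome(spec)
        bodies = {
            r.id: r.residues
            for r in extract_gene_bodies(
                list(bundle.genome), list(bundle.genes), mode="spliced"
            )
        }
        assert all(bodies[g.id] == g.residues for g in bundle.gene_sequences)

    def test_written_bundle_headers_carry_seed(self, tmp_path):
        spec = collembolan_like_spec(n_genes=5, seed=42)
        paths = generate_annotated_genome(spec).write(tmp_path / "toy")
        assert "seed=42" in paths["genome"].read_text()[:200]
        assert "seed=42" in paths["gff"].read_text()[:200]


class TestSpecValidation:
    def test_class_spec_bounds(self):
        with pytest.raises(ValueError):
            ClassSpec("x", 1.0, 0.0, 0.4)
        with pytest.raises(ValueError):
            ClassSpec("x", 1.0, 0.5, 0.99)
        with pytest.raises(ValueError):
            ClassSpec("x", 1.0, 0.5, 0.4, length_min=1)

    def test_proportions_must_sum_to_one(self):
        a = ClassSpec("a", 0.6, 0.5, 0.4)
        b = ClassSpec("b", 0.6, 0.5, 0.4)
        with pytest.raises(ValueError, match="sum to 1"):
            GenomeSimSpec(classes=(a, b), n_genes=10)
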