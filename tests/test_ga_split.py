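"""Stage-1 GA: variance fitness against a literal transliteration oracle,
stratification, elitism, determinism, and a small-instance exhaustive check."""

import itertools
import math

import numpy as np
import pytest

from epigram import (
    GAConfig,
    LabeledSequence,
    VarianceMaxSplitter,
    average_variance,
    build_feature_table,
    mutation_threshold,
    run_split_ga,
    solution_fitness,
)

from conftest import random_peptides


def eq4_scalar_oracle(a_vals, b_vals) -> float:
    """Direct loop transliteration of the directed deviation for scalars."""
    m, n = len(a_vals), len(b_vals)
    mean_b = sum(b_vals) / n
    sd_b = math.sqrt(sum((xj - mean_b) ** 2 for xj in b_vals) / (n - 1))
    center = sum(sd_b for _ in range(m)) / m  # inner sum over i is constant
    return math.sqrt(sum((xa - center) ** 2 for xa in a_vals) / (m - 1))


def directed_oracle(A, B) -> float:
    """Per-dimension scalar oracle averaged over dimensions."""
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    return float(
        np.mean([eq4_scalar_oracle(A[:, d], B[:, d]) for d in range(A.shape[1])])
    )


def fitness_oracle(table, train_idx) -> float:
    X = table.X.toarray()
    y = table.y[train_idx]
    vals = []
    for c in np.unique(y):
        a = X[train_idx[y == c]]
        b = X[train_idx[y != c]]
        vals.append(directed_oracle(a, b))
    return float(np.mean(vals))


class TestAverageVariance:
    def test_scalar_toy(self):
        """class_a={0,2}, class_b={1,1}: sd_b=0, so result is sd of {0,2}."""
        expected = eq4_scalar_oracle([0.0, 2.0], [1.0, 1.0])
        assert average_variance([0.0, 2.0], [1.0, 1.0]) == pytest.approx(expected)
        assert expected == pytest.approx(2.0)  # sqrt((0^2 + 2^2) / (2 - 1))

    def test_zero_when_class_a_constant_at_center(self):
        """All class-a values equal to class_b's sample std give zero."""
        sd_b = np.std([1.0, 3.0], ddof=1)
        assert average_variance([sd_b, sd_b, sd_b], [1.0, 3.0]) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_matches_oracle_on_random_matrices(self, rng):
        A = rng.random((5, 7)) * 10
        B = rng.random((4, 7)) * 10
        assert average_variance(A, B) == pytest.approx(directed_oracle(A, B))

    def test_positive_homogeneity_degree_one(self, rng):
        A, B = rng.random((4, 6)), rng.random((5, 6))
        v = average_variance(A, B)
        assert average_variance(3.0 * A, 3.0 * B) == pytest.approx(3.0 * v)

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            average_variance([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            average_variance([1.0, 2.0], [3.0])


class TestSolutionFitness:
    def test_binary_mean_of_directed_values(self, rng):
        seqs = random_peptides(rng, 8, lo=5, hi=12)
        seqs = [
            LabeledSequence(s.id, s.residues, label=i % 2)
            for i, s in enumerate(seqs)
        ]
        table = build_feature_table(seqs)
        idx = np.arange(8)
        assert solution_fitness(table, idx) == pytest.approx(
            fitness_oracle(table, idx)
        )

    def test_single_class_errors(self, rng):
        seqs = random_peptides(rng, 4, label=1)
        table = build_feature_table(seqs)
        with pytest.raises(ValueError):
            solution_fitness(table, np.arange(4))


def test_mutation_threshold():
    assert mutation_threshold([2.0, 4.0], 0.5) == pytest.approx(1.5)
    assert mutation_threshold([2.0, 4.0], 1.0) == pytest.approx(3.0)
    assert mutation_threshold([2.0, 4.0], 0.0) == 0.0
    with pytest.raises(ValueError):
        mutation_threshold([], 0.5)


def _toy_table(rng, n=20):
    seqs = random_peptides(rng, n, lo=6, hi=12)
    seqs = [
        LabeledSequence(s.id, s.residues, label=i % 2) for i, s in enumerate(seqs)
    ]
    return build_feature_table(seqs)


class TestRunSplitGA:
    def test_degenerate_single_solution(self, rng):
        table = _toy_table(rng)
        sol = run_split_ga(table, GAConfig(ns=1, ni=1, mu=0.2, tr=0.7, seed=5))
        assert sol.train_indices.size + sol.test_indices.size == table.n
        assert sol.fitness == pytest.approx(fitness_oracle(table, sol.train_indices))

    def test_stratified_equal_class_counts(self, rng):
        table = _toy_table(rng)
        sol = run_split_ga(table, GAConfig(ns=3, ni=2, mu=0.2, tr=0.7, seed=5))
        y_tr = table.y[sol.train_indices]
        assert (y_tr == 0).sum() == (y_tr == 1).sum()
        assert np.intersect1d(sol.train_indices, sol.test_indices).size == 0

    def test_elitism_trace_monotone(self, rng):
        table = _toy_table(rng, n=24)
        sol = run_split_ga(table, GAConfig(ns=4, ni=6, mu=0.9, tr=0.7, seed=7))
        assert all(b >= a for a, b in zip(sol.trace, sol.trace[1:]))
        assert sol.fitness == pytest.approx(max(sol.trace))

    def test_seed_determinism(self, rng):
        table = _toy_table(rng)
        cfg = GAConfig(ns=3, ni=3, mu=0.2, tr=0.7, seed=11)
        a = run_split_ga(table, cfg)
        b = run_split_ga(table, cfg)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)
        assert a.fitness == b.fitness

    def test_infeasible_ratio_errors_before_iterating(self, rng):
        table = _toy_table(rng, n=6)
        with pytest.raises(ValueError, match="training samples"):
            # tr=0.95 would need all rows of a class in training
            VarianceMaxSplitter(config=GAConfig(ns=1, ni=1, mu=0.2, tr=0.95)).fit(table)

    def test_small_instance_exhaustive_optimum(self, rng):
        """On 6 rows the GA (given enough draws) finds the enumerated optimum."""
        table = _toy_table(rng, n=6)
        pos = np.flatnonzero(table.y == 1)
        neg = np.flatnonzero(table.y == 0)
        best = -np.inf
        for p in itertools.combinations(pos, 2):
            for q in itertools.combinations(neg, 2):
                idx = np.sort(np.array(p + q))
                best = max(best, solution_fitness(table, idx))
        sol = run_split_ga(table, GAConfig(ns=5, ni=8, mu=0.2, tr=0.7, seed=3))
        assert sol.fitness == pytest.approx(best)

    def test_separation_sensitivity(self, rng):
        """Planted compositional separation yields higher split fitness than
        the same sequences with shuffled labels (majority of seeded runs)."""
        from epigram import SyntheticSpec, generate

        wins = 0
        for seed in range(8):
            spec = SyntheticSpec(
                n_pos=15, n_neg=15, length_range=(10, 20),
                signal_kmers=[("WWW", 1, 2.0)], seed=100 + seed,
            )
            seqs = generate(spec)
            sep_tab = build_feature_table(seqs)
            labels = sep_tab.y.copy()
            np.random.default_rng(seed).shuffle(labels)
            shuf = [
                LabeledSequence(s.id, s.residues, int(l))
                for s, l in zip(seqs, labels)
            ]
            shuf_tab = build_feature_table(shuf)
            cfg = GAConfig(ns=3, ni=3, mu=0.2, tr=0.7, seed=seed)
            if run_split_ga(sep_tab, cfg).fitness > run_split_ga(shuf_tab, cfg).fitness:
                wins += 1
        assert wins >= 6
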