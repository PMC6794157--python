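"""Haplotype-pair imputation against a reference table."""

import itertools

import numpy as np
import pytest

from qkat import (HaplotypeTable, LOCI, SimConfig, combined_frequency,
                  impute_all_pairs, impute_cohort, profile_from_pair,
                  sample_cohort, trim_best, write_imputation_outputs)
from qkat.calling import CopyNumberProfile
from qkat.haplotypes import Haplotype


def oracle_pairs(profile, table):
    """Independent brute-force enumerator (plain dict arithmetic)."""
    found = []
    for h1, h2 in itertools.combinations_with_replacement(table.haplotypes, 2):
        if all(h1.gene_content[l] + h2.gene_content[l] == profile[l] for l in LOCI):
            a, b = sorted((h1.name, h2.name))
            freq = combined_frequency(h1.frequency, h2.frequency, h1 is h2)
            found.append((a, b, freq))
    return sorted(found)


def test_aa_profile_imputes_exactly_the_a_pair(builtin_table):
    profile = profile_from_pair(builtin_table["A-2DS4FL"], builtin_table["A-2DS4FL"])
    assignment = impute_all_pairs(profile, builtin_table)
    assert assignment.status == "assigned"
    assert [(p[0], p[1]) for p in assignment.pairs] == [("A-2DS4FL", "A-2DS4FL")]


def test_framework_violation_is_unassignable(builtin_table):
    profile = profile_from_pair(builtin_table["A-2DS4FL"], builtin_table["A-2DS4Del"])
    profile["2DL4"] = 1   # framework loci sum to 2 in every pair
    assignment = impute_all_pairs(profile, builtin_table)
    assert assignment.status == "unassigned" and assignment.pairs == []


def test_empty_table_unassigned(builtin_table):
    profile = profile_from_pair(builtin_table["B-01"], builtin_table["B-02"])
    assert impute_all_pairs(profile, HaplotypeTable([])).status == "unassigned"


def test_enumerator_matches_independent_oracle(builtin_table):
    """Main (vectorised) enumerator vs plain-loop oracle on random profiles."""
    rng = np.random.default_rng(2024)
    haps = builtin_table.haplotypes
    for trial in range(100):
        if trial % 3 == 0:
            # random garbage profile, usually unassignable
            profile = {l: int(rng.integers(0, 4)) for l in LOCI}
        else:
            i, j = rng.integers(0, len(haps), size=2)
            profile = profile_from_pair(haps[i], haps[j])
        ours = sorted(impute_all_pairs(profile, builtin_table).pairs)
        assert ours == oracle_pairs(profile, builtin_table), profile


def test_wildcard_locus_relaxes_matching(builtin_table):
    profile = profile_from_pair(builtin_table["A-2DS4FL"], builtin_table["A-2DS4FL"])
    profile["2DS4FL"] = 9   # corrupt one locus
    assert impute_all_pairs(profile, builtin_table).status == "unassigned"
    relaxed = impute_all_pairs(profile, builtin_table,
                               wildcard_loci=frozenset({"2DS4FL"}))
    assert ("A-2DS4FL", "A-2DS4FL") in [(p[0], p[1]) for p in relaxed.pairs]


def test_symmetry_under_locus_column_permutation(builtin_table):
    rng = np.random.default_rng(7)
    haps = builtin_table.haplotypes
    perm = list(LOCI)
    rng.shuffle(perm)
    for _ in range(10):
        i, j = rng.integers(0, len(haps), size=2)
        profile = profile_from_pair(haps[i], haps[j])
        shuffled = {l: profile[l] for l in perm}
        assert sorted(impute_all_pairs(profile, builtin_table).pairs) == \
            sorted(impute_all_pairs(shuffled, builtin_table).pairs)


class TestTrimBest:
    def _assignment(self, pairs):
        from qkat.impute import PairAssignment
        return PairAssignment(sample_id="S1", pairs=pairs, status="assigned")

    def test_keeps_only_the_maximum(self):
        trimmed = trim_best(self._assignment([("a", "b", 0.04), ("c", "d", 0.01)]))
        assert trimmed.pairs == [("a", "b", 0.04)]
        assert trimmed.status == "trimmed_best"

    def test_ties_all_retained(self):
        trimmed = trim_best(self._assignment([("a", "b", 0.02), ("c", "d", 0.02)]))
        assert len(trimmed.pairs) == 2

    def test_single_pair_unchanged(self):
        trimmed = trim_best(self._assignment([("a", "a", 0.16)]))
        assert trimmed.pairs == [("a", "a", 0.16)]

    def test_unassigned_is_noop_with_warning(self):
        from qkat.impute import PairAssignment
        trimmed = trim_best(PairAssignment("S1", [], status="unassigned"))
        assert trimmed.status == "unassigned" and trimmed.warnings


def test_noise_free_recovery_meets_bayes_rate(builtin_table):
    """The true pair is always in the all-pairs list, and the fraction of
    samples whose trimmed-best entry equals the truth is at least the
    frequency-weighted Bayes rate over achievable profiles."""
    truth = sample_cohort(SimConfig(n_samples=96, seed=17))
    profiles = [CopyNumberProfile(s["sample_id"], s["profile"])
                for s in truth.samples]
    assignments = impute_cohort(profiles, builtin_table)

    # Bayes rate from the oracle: group all pairs by their profile and
    # accumulate the posterior mass of the best pair in each group.
    groups = {}
    for h1, h2 in itertools.combinations_with_replacement(builtin_table.haplotypes, 2):
        key = tuple(sorted(profile_from_pair(h1, h2).items()))
        freq = combined_frequency(h1.frequency, h2.frequency, h1 is h2)
        groups.setdefault(key, []).append(freq)
    bayes_rate = sum(max(fs) for fs in groups.values()) / \
        sum(f for fs in groups.values() for f in fs)

    n_correct = 0
    for s, asg in zip(truth.samples, assignments):
        true_pair = tuple(sorted((s["hap1"], s["hap2"])))
        assert true_pair in [(p[0], p[1]) for p in asg.pairs]
        best = [(p[0], p[1]) for p in trim_best(asg).pairs]
        n_correct += best == [true_pair]
    assert n_correct / len(assignments) >= bayes_rate - 1e-12


def test_output_files_roundtrip(tmp_path, builtin_table):
    truth = sample_cohort(SimConfig(n_samples=12, seed=3))
    profiles = [CopyNumberProfile(s["sample_id"], dict(s["profile"]))
                for s in truth.samples]
    profiles[5].copy_numbers["2DL4"] = 1    # make one sample unassignable
    assignments = impute_cohort(profiles, builtin_table)
    paths = write_imputation_outputs(assignments, tmp_path / "cohort")

    import pandas as pd
    all_pairs = pd.read_csv(paths["all"])
    best = pd.read_csv(paths["best"])
    unassigned = pd.read_csv(paths["unassigned"])
    assert set(unassigned["sample_id"]) == {profiles[5].sample_id}
    assert profiles[5].sample_id not in set(all_pairs["sample_id"])
    for sample_id, group in all_pairs.groupby("sample_id"):
        trimmed = best[best["sample_id"] == sample_id]
        assert 1 <= len(trimmed) <= len(group)
        assert trimmed["combined_frequency"].max() == group["combined_frequency"].max()


def test_fully_assignable_cohort_creates_empty_unassigned_file(tmp_path, builtin_table):
    truth = sample_cohort(SimConfig(n_samples=6, seed=9))
    assignments = impute_cohort(
        [CopyNumberProfile(s["sample_id"], s["profile"]) for s in truth.samples],
        builtin_table)
    paths = write_imputation_outputs(assignments, tmp_path / "clean")
    import pandas as pd
    assert paths["unassigned"].exists()
    assert len(pd.read_csv(paths["unassigned"])) == 0
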