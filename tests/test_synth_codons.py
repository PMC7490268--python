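"""The codon-alignment simulator and its ground truth."""

import numpy as np
import pytest
from scipy import stats

from sporefit.codes import standard_code
from sporefit.synth import CodonSimSpec, simulate_codon_alignment
from sporefit.trees import parse_newick

CODE = standard_code()


class TestSimulatorBasics:
    def test_zero_branch_lengths_leave_every_sequence_at_the_root(self):
        tree = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        sim = simulate_codon_alignment(
            CodonSimSpec(tree=tree, regime="M0", regime_params={"omega": 1.0},
                         n_sites=50, seed=0)
        )
        assert (sim.alignment.codons == sim.root_codons).all()
        assert sim.n_synonymous == sim.n_nonsynonymous == 0

    def test_identical_spec_and_seed_reproduce_byte_identical_alignments(self, tree4):
        spec = dict(tree=tree4, regime="M0", regime_params={"omega": 0.5},
                    n_sites=60, seed=123)
        a = simulate_codon_alignment(CodonSimSpec(**spec))
        b = simulate_codon_alignment(CodonSimSpec(**spec))
        assert (a.alignment.codons == b.alignment.codons).all()
        assert (a.site_classes == b.site_classes).all()

    def test_sequences_contain_only_sense_codons(self, tree4):
        sim = simulate_codon_alignment(
            CodonSimSpec(tree=tree4, regime="M0", regime_params={"omega": 2.0},
                         n_sites=100, seed=3)
        )
        assert sim.alignment.codons.min() >= 0
        assert sim.alignment.codons.max() < CODE.n_codons
        for taxon in sim.alignment.taxa:
            seq = sim.alignment.sequence(taxon)
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & CODE.stop_codons

    def test_invalid_specs_rejected(self, tree4):
        with pytest.raises(ValueError, match="regime"):
            CodonSimSpec(tree=tree4, regime="M9")
        with pytest.raises(ValueError, match="n_sites"):
            CodonSimSpec(tree=tree4, n_sites=0)
        with pytest.raises(ValueError, match="non-negative"):
            CodonSimSpec(tree=tree4, regime="M0", regime_params={"omega": -1})
        with pytest.raises(ValueError, match="proportions"):
            CodonSimSpec(tree=tree4, regime="branch_site",
                         regime_params={"p0": 0.8, "p1": 0.5, "omega0": 0.1,
                                        "omega2": 2.0})

    def test_taxa_tree_mismatch_impossible_by_construction(self, tree4):
        sim = simulate_codon_alignment(
            CodonSimSpec(tree=tree4, regime="M0", regime_params={"omega": 1.0},
                         n_sites=5, seed=1)
        )
        assert sim.alignment.taxa == tree4.taxa()


class TestSimulatorStatistics:
    def test_equal_frequency_root_draw_is_uniform_over_sense_codons(self):
        """Chi-square goodness of fit against uniform at alpha = 0.01."""
        tree = parse_newick("(A:0.0,B:0.0);")
        sim = simulate_codon_alignment(
            CodonSimSpec(tree=tree, regime="M0", regime_params={"omega": 1.0},
                         n_sites=20_000, seed=3)
        )
        counts = np.bincount(sim.root_codons, minlength=61)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_higher_omega_raises_nonsynonymous_to_synonymous_count_ratio(self):
        tree = parse_newick("(A:0.5,B:0.5);")
        ratios = {}
        for omega in (0.1, 5.0):
            sim = simulate_codon_alignment(
                CodonSimSpec(tree=tree, regime="M0", regime_params={"omega": omega},
                             n_sites=2000, seed=42)
            )
            ratios[omega] = sim.n_nonsynonymous / max(1, sim.n_synonymous)
        assert ratios[5.0] > ratios[0.1] * 5

    def test_pairwise_difference_oracle_agrees_with_event_counts_at_short_times(self):
        """At short branch lengths nearly every substitution survives as a
        single-nucleotide codon difference, so classifying observed pairwise
        differences is an independent check on the event counters."""
        tree = parse_newick("(A:0.01,B:0.01);")
        sim = simulate_codon_alignment(
            CodonSimSpec(tree=tree, regime="M0", regime_params={"omega": 0.8},
                         n_sites=5000, seed=9)
        )
        a, b = sim.alignment.codons
        syn = nonsyn = 0
        for i, j in zip(a, b):
            if i == j:
                continue
            ci, cj = CODE.codons[i], CODE.codons[j]
            if sum(x != y for x, y in zip(ci, cj)) == 1:
                if CODE.amino_acids[i] == CODE.amino_acids[j]:
                    syn += 1
                else:
                    nonsyn += 1
        assert abs(syn + nonsyn - (sim.n_synonymous + sim.n_nonsynonymous)) <= 0.05 * (
            sim.n_synonymous + sim.n_nonsynonymous
        )
        assert abs(nonsyn - sim.n_nonsynonymous) <= max(3, 0.1 * sim.n_nonsynonymous)

    def test_substitutions_per_site_scale_linearly_with_divergence(self):
        """The mean-rate-one scaling makes E[substitutions per codon] = t."""
        times = np.array([0.05, 0.2, 0.5, 1.0])
        observed = []
        for k, t in enumerate(times):
            tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
            sim = simulate_codon_alignment(
                CodonSimSpec(tree=tree, regime="M0", regime_params={"omega": 1.0},
                             n_sites=4000, seed=100 + k)
            )
            observed.append((sim.n_synonymous + sim.n_nonsynonymous) / 4000)
        slope = np.polyfit(times, observed, 1)[0]
        assert abs(slope - 1.0) < 0.08

    def test_branch_site_regime_labels_match_class_proportions(self, tree8):
        sim = simulate_codon_alignment(
            CodonSimSpec(
                tree=tree8, regime="branch_site",
                regime_params={"p0": 0.6, "p1": 0.3, "omega0": 0.1, "omega2": 4.0},
                n_sites=5000, seed=11,
            )
        )
        freq = np.bincount(sim.site_classes, minlength=4) / 5000
        # classes: 0, 1, 2a, 2b with the 0.1 remainder split 2:1
        assert np.allclose(freq, [0.6, 0.3, 0.0667, 0.0333], atol=0.02)
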