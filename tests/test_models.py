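"""Model fitting, likelihood-ratio tests, site posteriors, selection calls."""

import numpy as np
import pytest
from scipy.stats import chi2

from sporefit.alignment import CodonAlignment
from sporefit.selection import (
    OMEGA_CAP,
    classify_selection,
    fit,
    lrt,
    model_site_classes,
    positive_site_report,
    site_posteriors,
)
from sporefit.synth import CodonSimSpec, simulate_codon_alignment
from sporefit.trees import parse_newick


class TestSiteClassTables:
    def test_np_convention_matches_model_hierarchy(self, m0_alignment, tree8):
        # quick fixed-branch fits just to read off the bookkeeping
        aln = m0_alignment.alignment
        fits = {
            m: fit(aln, tree8, m, freq_mode="equal", fix_branch_lengths=True,
                   n_starts=1, max_iter=5)
            for m in ("M0", "two_ratio", "modelA_null", "modelA")
        }
        assert [fits[m].np_omega for m in ("M0", "two_ratio", "modelA_null", "modelA")] == [1, 2, 3, 4]

    def test_class_proportions_sum_to_one_with_proportional_split(self):
        classes = model_site_classes(
            "modelA", {"p0": 0.5, "p1": 0.25, "omega0": 0.1, "omega2": 4.0}
        )
        weights = [w for w, _, _ in classes]
        assert np.isclose(sum(weights), 1.0)
        # remainder 0.25 split 2:1 between classes 2a and 2b
        assert np.isclose(weights[2] / weights[3], 2.0)
        # class 2 has background omega0 or 1 and foreground omega2
        assert classes[2][1:] == (0.1, 4.0)
        assert classes[3][1:] == (1.0, 4.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            model_site_classes("M8", {})


class TestFitting:
    def test_m0_recovers_simulated_omega(self, m0_alignment, tree8):
        f = fit(m0_alignment.alignment, tree8, "M0", freq_mode="equal", n_starts=1)
        assert f.converged
        assert 0.2 < f.params["omega"] < 0.42  # truth 0.3 at L = 400
        assert 1.4 < f.kappa < 2.8  # truth 2.0

    def test_nested_models_never_lose_likelihood(self, m0_alignment, tree8):
        aln = m0_alignment.alignment
        kw = dict(freq_mode="equal", fix_branch_lengths=True, n_starts=1)
        m0 = fit(aln, tree8, "M0", **kw)
        tr = fit(aln, tree8, "two_ratio", **kw)
        an = fit(aln, tree8, "modelA_null", **kw)
        aa = fit(aln, tree8, "modelA", **kw)
        tol = 1e-3  # optimizer path noise at the boundary
        assert tr.lnL >= m0.lnL - tol
        assert aa.lnL >= an.lnL - tol

    def test_branch_model_requires_foreground_tags(self, m0_alignment):
        untagged = parse_newick(
            "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,"
            "((E:0.1,F:0.1):0.1,(G:0.1,H:0.1):0.1):0.1);"
        )
        with pytest.raises(ValueError, match="foreground"):
            fit(m0_alignment.alignment, untagged, "two_ratio")

    def test_foreground_without_synonymous_change_reports_capped_omega(self):
        """All-nonsynonymous divergence on the foreground drives omega to the
        dS-zero reporting convention (999.0)."""
        tree = parse_newick("(A:0.02,B:0.02,C:0.4 #1);")
        # C differs from A and B only by nonsynonymous first-position changes:
        # AAA (K) -> CAA (Q) etc.; A and B are identical.
        base = "AAAGATTTGCTGATGCCC"
        fg = "CAAAATATGATGACGGCC"
        aln = CodonAlignment.from_sequences([("A", base), ("B", base), ("C", fg)])
        f = fit(aln, tree, "two_ratio", freq_mode="equal", n_starts=1)
        assert f.params["omega1"] == OMEGA_CAP
        assert f.ds_zero


class TestLRT:
    def test_identical_likelihoods_give_zero_statistic_p_one(self, m0_alignment, tree8):
        kw = dict(freq_mode="equal", fix_branch_lengths=True, n_starts=1)
        m0 = fit(m0_alignment.alignment, tree8, "M0", **kw)
        tr = fit(m0_alignment.alignment, tree8, "two_ratio", **kw)
        tr.lnL = m0.lnL  # force the degenerate case
        stat, df, p = lrt(m0, tr)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_chi_square_closed_form(self, m0_alignment, tree8):
        kw = dict(freq_mode="equal", fix_branch_lengths=True, n_starts=1)
        m0 = fit(m0_alignment.alignment, tree8, "M0", **kw)
        tr = fit(m0_alignment.alignment, tree8, "two_ratio", **kw)
        tr.lnL = m0.lnL + 3.84 / 2
        stat, df, p = lrt(m0, tr)
        assert df == 1
        assert np.isclose(p, chi2.sf(3.84, 1), atol=1e-12)
        assert round(p, 3) == 0.050

    def test_non_nested_pair_rejected(self, m0_alignment, tree8):
        kw = dict(freq_mode="equal", fix_branch_lengths=True, n_starts=1, max_iter=5)
        m0 = fit(m0_alignment.alignment, tree8, "M0", **kw)
        an = fit(m0_alignment.alignment, tree8, "modelA_null", **kw)
        with pytest.raises(ValueError, match="nested"):
            lrt(m0, an)
        with pytest.raises(ValueError, match="nested"):
            lrt(an, m0)


@pytest.fixture(scope="module")
def planted_fit():
    """Model A fit on data with a strongly selected foreground class."""
    tree = parse_newick(
        "(((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.1,"
        "((E:0.1,F:0.1):0.1,(G:0.1,H:0.1) #1:1.0):0.1);"
    )
    sim = simulate_codon_alignment(
        CodonSimSpec(
            tree=tree, regime="branch_site",
            regime_params={"p0": 0.55, "p1": 0.2, "omega0": 0.05, "omega2": 10.0},
            n_sites=300, seed=17,
        )
    )
    f = fit(sim.alignment, tree, "modelA", freq_mode="equal",
            fix_branch_lengths=True, n_starts=1)
    return sim, f


class TestSitePosteriors:
    def test_posteriors_normalize_per_site(self, planted_fit):
        _, f = planted_fit
        post = site_posteriors(f)
        assert post.shape[1] == 4
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-12

    def test_planted_selected_sites_rank_above_conserved_sites(self, planted_fit):
        sim, f = planted_fit
        post = site_posteriors(f)
        p2 = post[:, 2] + post[:, 3]
        selected = sim.site_classes >= 2
        conserved = sim.site_classes == 0
        assert p2[selected].mean() > p2[conserved].mean() + 0.2

    def test_site_report_tokens_are_position_plus_reference_residue(self, planted_fit):
        sim, f = planted_fit
        report = positive_site_report(f, "A", threshold=0.7)
        assert report, "expected at least one high-posterior site"
        ref = sim.alignment.sequence("A")
        code = sim.alignment.code
        for token, prob in report:
            pos = int(token[:-1])
            assert token[-1] == code.translate(ref[3 * (pos - 1) : 3 * pos])
            assert 0.7 <= prob <= 1.0

    def test_posteriors_undefined_for_m0(self, m0_alignment, tree8):
        f = fit(m0_alignment.alignment, tree8, "M0", freq_mode="equal",
                fix_branch_lengths=True, n_starts=1, max_iter=5)
        with pytest.raises(ValueError, match="undefined"):
            site_posteriors(f)


class TestSelectionCalls:
    @pytest.mark.parametrize(
        "omega,ds_zero,label",
        [
            (0.242, False, "purifying"),
            (0.373, False, "purifying"),
            (999.0, True, "positive"),
            (1.0, False, "neutral_boundary"),
            (3.4, False, "positive"),
        ],
    )
    def test_labels_follow_omega_rule(self, omega, ds_zero, label):
        call = classify_selection(omega, ds_zero)
        assert call.label == label
        assert call.ds_zero is ds_zero

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            classify_selection(-0.1)
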