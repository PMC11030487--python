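"""Malignancy index: DEGs, axis-gene selection, curve ordering, dynamics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pcttools.axis import (
    HEALTHY_ANCHOR,
    build_axis,
    composition_trend,
    expression_dynamics,
    sample_degs,
    select_axis_genes,
)
from pcttools.preprocess import lognorm
from pcttools._stats import rank_sum_rows


def exact_rank_sum_p(x, y):
    """Exhaustive-enumeration two-sided rank-sum p-value (tie-free input)."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    obs = ranks[: len(x)].sum()
    n = len(pooled)
    stats = [sum(c) for c in itertools.combinations(ranks, len(x))]
    mean = np.mean(stats)
    p = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats])
    return p


class TestWilcoxonAgainstEnumeration:
    @pytest.mark.parametrize(
        "x,y",
        [
            ([5, 6, 7], [1, 2, 3]),
            ([1, 4, 6, 9], [2, 3, 5]),
            ([10, 20, 30, 40, 50], [15, 25, 35]),
            ([1, 2], [3, 4, 5, 6]),
        ],
    )
    def test_matches_exact_enumeration(self, x, y):
        p = rank_sum_rows(np.array([x], dtype=float), np.array([y], dtype=float))[0]
        assert p == pytest.approx(exact_rank_sum_p(np.array(x), np.array(y)), abs=1e-9)

    def test_identical_groups_give_p_one_and_zero_fc(self, small_atlas):
        _, counts, meta, _, _ = small_atlas
        x = np.ones((5, 4))
        assert np.all(rank_sum_rows(x, x) == 1.0)


class TestSampleDEGs:
    def test_tidy_table_and_skip_warning(self, medium_atlas):
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        degs = sample_degs(norm, counts.gene_names, meta)
        diseased = meta.loc[meta["stage"] != "healthy", "sample_id"].nunique()
        assert degs["sample_id"].nunique() == diseased
        assert ((degs["fdr"] >= degs["p_value"] - 1e-12) | degs["fdr"].isna()).all()
        assert degs["p_value"].between(0, 1).all()

    def test_planted_fold_changes_positive_for_transition_genes(self, medium_atlas):
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        degs = sample_degs(norm, counts.gene_names, meta)
        cancer_samples = meta.loc[meta["stage"] == "cancer", "sample_id"].unique()
        sub = degs[degs["sample_id"].isin(cancer_samples) & degs["gene"].isin(truth.transition_genes["gene"])]
        assert (sub["log2fc"] > 0).mean() > 0.95


class TestAxisGeneSelection:
    def _degs(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "log2fc", "p_value", "fdr"])

    def test_single_sample_significance_excluded(self):
        degs = self._degs(
            [("s1", "A", 2.0, 1e-5, 1e-4), ("s2", "A", 0.1, 0.9, 0.9), ("s1", "B", 1.0, 1e-4, 1e-3), ("s2", "B", 1.0, 1e-4, 1e-3)]
        )
        assert list(select_axis_genes(degs)) == ["B"]

    def test_boundary_values_included(self):
        degs = self._degs([("s1", "A", 0.5, 0.01, 0.05), ("s2", "A", -0.5, 0.01, 0.05)])
        assert list(select_axis_genes(degs)) == ["A"]

    def test_empty_selection_raises(self):
        degs = self._degs([("s1", "A", 0.1, 0.9, 0.9)])
        with pytest.raises(ValueError, match="significant"):
            select_axis_genes(degs)

    def test_recovers_planted_transition_genes(self, medium_atlas):
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        degs = sample_degs(norm, counts.gene_names, meta)
        genes = set(select_axis_genes(degs))
        planted = set(truth.transition_genes["gene"])
        assert len(genes & planted) / len(planted) >= 0.9


class TestBuildAxis:
    def _collinear_degs(self, mags):
        rows = []
        for sid, m in zip("abcdef", mags):
            for g, w in [("g1", 1.0), ("g2", 0.5), ("g3", -0.25)]:
                rows.append((sid, g, m * w, 1e-4, 1e-3))
        return pd.DataFrame(rows, columns=["sample_id", "gene", "log2fc", "p_value", "fdr"])

    def test_collinear_samples_ordered_by_magnitude(self):
        degs = self._collinear_degs([0.5, 1.0, 2.0, 3.0])
        ax = build_axis(degs, np.array(["g1", "g2", "g3"]))
        assert ax.fallback_pc1
        pos = ax.position
        assert pos[HEALTHY_ANCHOR] == 0.0
        assert pos["a"] < pos["b"] < pos["c"] < pos["d"] == 1.0

    def test_identical_samples_share_position(self):
        degs = self._collinear_degs([1.0, 1.0, 2.0, 3.0])
        ax = build_axis(degs, np.array(["g1", "g2", "g3"]))
        assert ax.position["a"] == pytest.approx(ax.position["b"], abs=1e-9)

    def test_anchor_zero_and_max_one(self, medium_atlas):
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        degs = sample_degs(norm, counts.gene_names, meta)
        ax = build_axis(degs, select_axis_genes(degs))
        assert ax.position[HEALTHY_ANCHOR] == 0.0
        assert ax.position.max() == 1.0
        assert ax.position.between(0, 1).all()

    def test_sample_order_permutation_invariance(self, medium_atlas):
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        degs = sample_degs(norm, counts.gene_names, meta)
        genes = select_axis_genes(degs)
        ax1 = build_axis(degs, genes)
        shuffled = degs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        ax2 = build_axis(shuffled, genes)
        pd.testing.assert_series_equal(
            ax1.position.sort_index(), ax2.position.sort_index(), atol=1e-9
        )

    def test_too_few_samples_raises(self):
        degs = self._collinear_degs([1.0, 2.0])
        with pytest.raises(ValueError, match="samples"):
            build_axis(degs, np.array(["g1", "g2", "g3"]))

    def test_recovers_planted_sample_ordering(self, medium_atlas):
        """Headline parameter-recovery: Spearman(position, planted sample
        malignancy) >= 0.9 over all samples (healthy anchored at 0)."""
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        degs = sample_degs(norm, counts.gene_names, meta)
        ax = build_axis(degs, select_axis_genes(degs))
        stages = meta.groupby("sample_id")["stage"].first()
        pos = ax.positions_for(stages.index.to_numpy(), stages.to_numpy())
        planted = np.array([truth.sample_malignancy[s] for s in pos.index])
        rho = scipy.stats.spearmanr(pos.to_numpy(), planted).statistic
        assert rho >= 0.9


class TestExpressionDynamics:
    def _axis_and_degs(self, fcs):
        rows = [(f"s{i}", "g", fc, 1e-4, 1e-3) for i, fc in enumerate(fcs)]
        rows += [(f"s{i}", "h", 0.6, 1e-4, 1e-3) for i in range(len(fcs))]
        degs = pd.DataFrame(rows, columns=["sample_id", "gene", "log2fc", "p_value", "fdr"])
        ax = build_axis(degs, np.array(["g", "h"]))
        return ax, degs

    def test_constant_fold_change_gives_flat_smooth(self):
        # gene g spreads the samples along the axis; gene h is constant at 0.6
        ax, degs = self._axis_and_degs([0.1, 0.5, 1.0, 1.5, 2.0, 2.5])
        curve = expression_dynamics(ax, degs, "h")
        np.testing.assert_allclose(curve["smooth"], 0.6, atol=1e-9)

    def test_monotone_gene_gives_monotone_smooth(self, medium_atlas):
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        degs = sample_degs(norm, counts.gene_names, meta)
        ax = build_axis(degs, select_axis_genes(degs))
        rhos, rises = [], []
        for gene in truth.transition_genes["gene"].iloc[:10]:
            curve = expression_dynamics(ax, degs, gene)
            smooth = curve["smooth"].to_numpy()
            rhos.append(scipy.stats.spearmanr(curve["position"], smooth).statistic)
            rises.append(smooth[-1] - smooth[0])
            assert (np.diff(smooth) >= -0.1).all()  # only negligible local dips
        assert np.mean(rhos) >= 0.9  # strongly increasing overall
        assert min(rises) > 0.3

    def test_absent_gene_raises(self):
        ax, degs = self._axis_and_degs([0.1, 0.5, 1.0, 2.0])
        with pytest.raises(KeyError):
            expression_dynamics(ax, degs, "missing")


class TestCompositionTrend:
    def test_fractions_sum_to_one_and_stem_trend_recovered(self, medium_atlas):
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        degs = sample_degs(norm, counts.gene_names, meta)
        ax = build_axis(degs, select_axis_genes(degs))
        stages = meta.groupby("sample_id")["stage"].first()
        pos = ax.positions_for(stages.index.to_numpy(), stages.to_numpy())
        frac, trend = composition_trend(pos, meta)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)
        stem = trend.set_index("cell_type").loc["STM"]
        assert stem["rho"] > 0 and stem["fdr"] < 0.05
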