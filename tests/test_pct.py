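"""Four-way candidate sets and the geometric-mean PCT signature."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from pcttools._stats import bh_fdr, spearman_rows
from pcttools.pct import (
    CandidateSets,
    derive_pct,
    mp_genes,
    pseudo_bulk_degs,
    subcluster_degs,
    transition_genes,
)
from pcttools.preprocess import lognorm


def _cand(pb, sub, trans_rho, mp_rho=None):
    trans = pd.DataFrame({"gene": list(trans_rho), "rho": list(trans_rho.values()), "fdr": 0.01})
    mp_rho = mp_rho if mp_rho is not None else trans_rho
    mp = pd.DataFrame({"gene": list(mp_rho), "rho": list(mp_rho.values()), "fdr": 0.01})
    return CandidateSets(set(pb), set(sub), trans, mp)


class TestSpearmanScreen:
    def test_six_point_toy_matches_direct_computation(self):
        """expr ranks (1..6) vs time ranks (2,1,3,5,4,6): sum d^2 = 4,
        rho = 1 - 24/210 = 0.8857; cross-checked against scipy."""
        expr = np.array([[1, 2, 3, 4, 5, 6]], dtype=float)
        t = np.array([2, 1, 3, 5, 4, 6], dtype=float)
        rho, p = spearman_rows(expr, t)
        direct = 1 - 6 * 4 / (6 * 35)
        assert rho[0] == pytest.approx(direct, abs=1e-12)
        ref = scipy.stats.spearmanr(expr[0], t)
        assert rho[0] == pytest.approx(ref.statistic, abs=1e-12)
        assert p[0] == pytest.approx(ref.pvalue, abs=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 8])
    def test_matches_scipy_on_small_vectors(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=(3, n))
        y = rng.normal(size=n)
        rho, p = spearman_rows(x, y)
        for i in range(3):
            ref = scipy.stats.spearmanr(x[i], y)
            assert rho[i] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[i] == pytest.approx(ref.pvalue, abs=1e-9)


class TestBHAgainstEnumeration:
    @pytest.mark.parametrize("m", [3, 6, 10])
    def test_matches_step_up_definition(self, m):
        """BH adjusted p: running minimum of p_(i) * m / i from the top."""
        rng = np.random.default_rng(m)
        p = rng.uniform(0, 1, m)
        got = bh_fdr(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            adj[order[rank - 1]] = running
        np.testing.assert_allclose(got, adj, atol=1e-12)


class TestPseudoBulkDEGs:
    def _meta(self, n_h, n_d, cells_per=30):
        rows = []
        for s in range(n_h):
            rows += [{"sample_id": f"h{s}", "stage": "healthy", "cell_type": "STM"}] * cells_per
        for s in range(n_d):
            rows += [{"sample_id": f"d{s}", "stage": "cancer", "cell_type": "STM"}] * cells_per
        return pd.DataFrame(rows)

    def test_constant_gene_excluded(self):
        meta = self._meta(4, 4)
        x = np.ones((3, len(meta)))
        genes, table = pseudo_bulk_degs(sp.csr_matrix(x), np.array(["a", "b", "c"]), meta)
        assert genes == set()
        assert (table["p_value"] == 1.0).all()

    def test_exact_boundary_fold_change_excluded(self):
        meta = self._meta(4, 4, cells_per=10)
        n = len(meta)
        x = np.zeros((2, n))
        healthy = (meta["stage"] == "healthy").to_numpy()
        # gene 0: de-logged pseudo-bulk means 1 (healthy) vs 2^0.25*2-1 (diseased)
        x[0, healthy] = np.log(2.0)
        x[0, ~healthy] = np.log(2.0 ** 0.25 * 2.0)
        genes, table = pseudo_bulk_degs(sp.csr_matrix(x), np.array(["g0", "g1"]), meta)
        assert table.set_index("gene").loc["g0", "log2fc"] == pytest.approx(0.25, abs=1e-12)
        assert "g0" not in genes  # strict > 0.25

    def test_too_few_samples_raises(self):
        meta = self._meta(2, 4)
        with pytest.raises(ValueError, match="samples per side"):
            pseudo_bulk_degs(sp.csr_matrix(np.ones((2, len(meta)))), np.array(["a", "b"]), meta)

    def test_planted_upregulation_recovered(self, medium_atlas):
        _, counts, meta, _, truth = medium_atlas
        norm = lognorm(counts.matrix)
        stem_meta = meta.assign(
            cell_type=np.where(truth.cell_type == "STM", "STM", "other")
        )
        genes, _ = pseudo_bulk_degs(norm, counts.gene_names, stem_meta)
        planted = set(truth.transition_genes["gene"])
        assert len(genes & planted) / len(planted) >= 0.6


class TestSubclusterDEGs:
    def _toy(self):
        # 2 clusters x 20 cells; gene0: 30% vs 10% detection with strong fc
        rng = np.random.default_rng(0)
        x = np.zeros((3, 40))
        x[0, :6] = 2.0  # 30% of cluster 0
        x[0, 20:22] = 2.0  # 10% of cluster 1
        x[1, :4] = 1.0  # pct.1 = 0.2 -> fails regardless of fc
        x[2, :20] = 1.0
        x[2, 20:] = 1.0  # equal in both
        labels = np.array([0] * 20 + [1] * 20)
        return sp.csr_matrix(x), np.array(["hi", "low_pct", "flat"]), labels

    def test_rule_application(self):
        x, names, labels = self._toy()
        genes, table = subcluster_degs(x, names, labels, [(0, 1)])
        assert genes == {"hi"}
        t = table.set_index("gene")
        assert t.loc["hi", "pct_ratio"] == pytest.approx(3.0)
        assert t.loc["low_pct", "pct_1"] == pytest.approx(0.2)
        assert t.loc["flat", "pct_ratio"] == pytest.approx(1.0)

    def test_unknown_cluster_raises(self):
        x, names, labels = self._toy()
        with pytest.raises(ValueError, match="unknown cluster"):
            subcluster_degs(x, names, labels, [(0, 7)])


class TestTransitionGenes:
    def test_gene_equal_to_pseudotime_kept_with_rho_one(self):
        rng = np.random.default_rng(1)
        pt = rng.uniform(0, 1, 60)
        x = np.vstack([pt, np.ones(60)])
        out = transition_genes(sp.csr_matrix(x), np.array(["follow", "const"]), pt)
        assert list(out["gene"]) == ["follow"]
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_pseudotime_raises(self):
        with pytest.raises(ValueError, match="constant"):
            transition_genes(sp.csr_matrix(np.ones((2, 40))), np.array(["a", "b"]), np.ones(40))

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError, match="cells"):
            transition_genes(
                sp.csr_matrix(np.ones((2, 10))), np.array(["a", "b"]), np.linspace(0, 1, 10)
            )


class TestMPGenes:
    def test_noise_gene_type_i_control(self):
        """Across seeded replicates, an activity-independent noise gene is
        excluded by the FDR screen in >= 95% of runs."""
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(100 + s)
            act = rng.uniform(0, 1, 500)
            x = np.vstack([act + rng.normal(0, 0.05, 500), rng.normal(0, 1, 500)])
            out = mp_genes(sp.csr_matrix(x), np.array(["driver", "noise"]), act)
            assert "driver" in set(out["gene"])
            if "noise" in set(out["gene"]):
                hits += 1
        assert hits / n_rep <= 0.05

    def test_constant_activity_raises(self):
        with pytest.raises(ValueError, match="constant"):
            mp_genes(sp.csr_matrix(np.ones((2, 50))), np.array(["a", "b"]), np.ones(50))


class TestDerivePCT:
    def test_truncation_to_top_100(self):
        rho = {f"g{i:03d}": 0.99 - i * 0.005 for i in range(150)}
        cand = _cand(rho, rho, rho)
        sig = derive_pct({"t1": cand}, "MP0")
        assert len(sig.genes) == 100
        expected = sorted(rho, key=lambda g: (-rho[g], g))[:100]
        assert list(sig.genes) == expected
        assert (np.diff(sig.gmean_score) <= 1e-12).all()

    def test_two_tissue_geometric_mean(self):
        c1 = _cand({"g"}, {"g"}, {"g": 0.4})
        c2 = _cand({"g"}, {"g"}, {"g": 0.9})
        sig = derive_pct({"t1": c1, "t2": c2}, "MP0")
        assert sig.gmean_score[0] == pytest.approx(0.6)

    def test_gene_with_nonpositive_rho_everywhere_dropped(self):
        cand = _cand({"g", "h"}, {"g", "h"}, {"g": -0.3, "h": 0.5})
        sig = derive_pct({"t1": cand}, "MP0")
        assert list(sig.genes) == ["h"]

    def test_output_subset_of_union_of_intersections(self):
        c1 = _cand({"a", "b"}, {"b", "c"}, {"a": 0.5, "b": 0.5, "c": 0.5})
        c2 = _cand({"d"}, {"d"}, {"d": 0.2})
        sig = derive_pct({"t1": c1, "t2": c2}, "MP0")
        assert set(sig.genes) <= {"b", "d"}

    def test_increasing_rho_never_lowers_rank(self):
        base = {"x": 0.3, "y": 0.5, "z": 0.4}
        sig1 = derive_pct({"t": _cand(base, base, base)}, "MP0")
        boosted = dict(base, x=0.9)
        sig2 = derive_pct({"t": _cand(boosted, boosted, boosted)}, "MP0")
        assert list(sig1.genes).index("x") >= list(sig2.genes).index("x")

    def test_empty_intersections_warn_empty_signature(self):
        cand = _cand({"a"}, {"b"}, {"c": 0.5})
        with pytest.warns(UserWarning, match="empty"):
            sig = derive_pct({"t1": cand}, "MP0")
        assert sig.genes.size == 0
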