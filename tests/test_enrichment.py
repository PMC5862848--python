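import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from probescout.digestion import PeptideInterval
from probescout.enrichment import (
    FeatureEnrichment,
    bh_adjust,
    count_features,
    filter_min_features,
    moderated_t,
    voom,
    volcano_table,
)
from probescout.site_id import PSM


def psm(pid, seq, charge, sample, i=[0]):
    i[0] += 1
    return PSM(
        spectrum_id=f"s{i[0]}",
        protein_id=pid,
        peptide=PeptideInterval(pid, 0, len(seq), seq),
        mods=(),
        charge=charge,
        score=10.0,
        sample_id=sample,
        replicate="R1",
    )


DESIGN = np.column_stack([np.ones(6), np.array([1.0, 1, 1, 0, 0, 0])])


def nb_counts(rng, mu, phi, shape):
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + mu), size=shape)


class TestCountFeatures:
    def test_charge_states_are_distinct_features(self):
        psms = [psm("P1", "ACDEFK", 2, "s1"), psm("P1", "ACDEFK", 3, "s1")]
        counts = count_features(psms)
        assert counts.loc["P1", "s1"] == 2

    def test_identical_forms_collapse(self):
        psms = [psm("P1", "ACDEFK", 2, "s1"), psm("P1", "ACDEFK", 2, "s1")]
        assert count_features(psms).loc["P1", "s1"] == 1

    def test_no_psms_empty(self):
        assert count_features([]).empty


class TestFilterMinFeatures:
    @pytest.mark.parametrize("total,kept", [(2, False), (3, True)])
    def test_row_sum_threshold(self, total, kept):
        m = pd.DataFrame([[total, 0, 0, 0, 0, 0]], index=["P1"])
        out = filter_min_features(m, 3)
        assert ("P1" in out.index) == kept

    def test_all_zero_matrix_empties(self):
        m = pd.DataFrame(np.zeros((4, 6), dtype=int))
        assert filter_min_features(m, 3).empty


class TestVoom:
    def test_log_cpm_formula_zero_count(self):
        # one zero-count protein against a library of 999999:
        # y = log2((0+0.5)/(999999+1) * 1e6) = -1
        counts = np.tile([[0], [999999]], (1, 6))
        with pytest.warns(UserWarning):
            vt = voom(counts, DESIGN)
        assert np.allclose(vt.y[0], -1.0)

    def test_weights_strictly_positive(self, rng):
        counts = nb_counts(rng, 50.0, 0.3, (80, 6))
        vt = voom(counts, DESIGN)
        assert (vt.weights > 0).all()

    def test_invariant_to_protein_order(self, rng):
        counts = nb_counts(rng, 50.0, 0.3, (40, 6))
        perm = rng.permutation(40)
        vt1 = voom(counts, DESIGN)
        vt2 = voom(counts[perm], DESIGN)
        assert np.allclose(vt1.y[perm], vt2.y)
        assert np.allclose(vt1.weights[perm], vt2.weights)

    def test_single_sample_condition_rejected(self):
        design = np.column_stack([np.ones(2), [1.0, 0.0]])
        with pytest.raises(ValueError):
            voom(np.ones((5, 2)), design)


def oracle_moderated(y, w, design, d0_override=None):
    """Independent direct-formula implementation: per-protein WLS loops plus
    moment-matching of log s^2 through explicit digamma/trigamma algebra."""
    G, n = y.shape
    p = design.shape[1]
    dof = n - p
    beta = np.zeros(G)
    s2 = np.zeros(G)
    u = np.zeros(G)
    for g in range(G):
        W = np.diag(w[g])
        A = design.T @ W @ design
        b = np.linalg.solve(A, design.T @ W @ y[g])
        r = y[g] - design @ b
        s2[g] = float(r @ W @ r) / dof
        beta[g] = b[1]
        u[g] = np.sqrt(np.linalg.inv(A)[1, 1])
    if d0_override is not None:
        d0 = d0_override
        s02 = np.exp(np.mean(np.log(s2)))
    else:
        z = np.log(s2)
        evar = np.var(z, ddof=1) - special.polygamma(1, dof / 2)
        from scipy.optimize import brentq

        half = brentq(lambda h: special.polygamma(1, h) - evar, 1e-6, 1e8)
        d0 = 2 * half
        s02 = np.exp(np.mean(z - special.digamma(dof / 2) + np.log(dof / 2))
                     + special.digamma(half) - np.log(half))
    s2_post = (d0 * s02 + dof * s2) / (d0 + dof)
    t = beta / (u * np.sqrt(s2_post))
    pval = 2 * stats.t.sf(np.abs(t), d0 + dof)
    return beta, s2_post, t, pval


class TestModeratedT:
    def test_equal_group_means_give_null_stats(self):
        y = np.tile(np.array([5.0, 6, 7, 5, 6, 7]), (4, 1))
        y += np.arange(4)[:, None]  # distinct levels, identical group effects
        w = np.ones_like(y)
        from probescout.enrichment import VoomTransform

        vt = VoomTransform(y, w, np.zeros(4), np.ones(4), np.ones(6))
        mf = moderated_t(vt, DESIGN, d0_override=0.0)
        assert np.allclose(mf.coef, 0.0, atol=1e-12)
        assert np.allclose(mf.t, 0.0, atol=1e-10)
        assert np.allclose(mf.p, 1.0)

    def test_agrees_with_direct_formula_oracle(self, rng):
        # heterogeneous abundance and dispersion so the prior df is finite
        mu = rng.uniform(5, 500, size=40)[:, None]
        phi = rng.uniform(0.05, 2.0, size=40)[:, None]
        counts = nb_counts(rng, mu, phi, (40, 6))
        vt = voom(counts, DESIGN)
        mf = moderated_t(vt, DESIGN)
        assert np.isfinite(mf.d0)
        beta, s2_post, t, p = oracle_moderated(vt.y, vt.weights, DESIGN)
        assert np.allclose(mf.coef, beta, atol=1e-8)
        assert np.allclose(mf.sigma2_post, s2_post, atol=1e-6)
        assert np.allclose(mf.t, t, atol=1e-6)
        assert np.allclose(mf.p, p, atol=1e-6)

    def test_d0_zero_recovers_ordinary_weighted_t(self, rng):
        counts = nb_counts(rng, 50.0, 0.3, (30, 6))
        vt = voom(counts, DESIGN)
        mf = moderated_t(vt, DESIGN, d0_override=0.0)
        beta, s2_post, t, p = oracle_moderated(vt.y, vt.weights, DESIGN, 0.0)
        assert np.allclose(mf.sigma2_post, mf.sigma2)
        assert np.allclose(mf.t, t, atol=1e-8)

    def test_d0_infinity_shares_one_variance(self, rng):
        counts = nb_counts(rng, 50.0, 0.3, (30, 6))
        vt = voom(counts, DESIGN)
        mf = moderated_t(vt, DESIGN, d0_override=np.inf)
        assert np.allclose(mf.sigma2_post, mf.sigma2_post[0])

    def test_all_zero_variance_is_an_error(self):
        from probescout.enrichment import VoomTransform

        y = np.tile(np.arange(6.0), (4, 1)) * 0 + 3.0
        vt = VoomTransform(y, np.ones_like(y), np.zeros(4), np.ones(4), np.ones(6))
        with pytest.raises(ValueError):
            moderated_t(vt, DESIGN)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.02])[0] == pytest.approx(0.02)

    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_order_preserving(self, rng):
        p = rng.uniform(1e-6, 1.0, size=50)
        q = bh_adjust(p)
        assert np.all(np.sign(np.diff(q[np.argsort(p)])) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestFeatureEnrichmentModel:
    def make_model(self, rng, effect_rows=0, effect=3.0, n=120):
        mu = np.full((n, 6), 50.0)
        mu[:effect_rows, :3] *= 2.0**effect
        counts = pd.DataFrame(
            nb_counts(rng, mu, 0.2, (n, 6)),
            index=[f"P{i}" for i in range(n)],
            columns=["probe_1", "probe_2", "probe_3",
                     "control_1", "control_2", "control_3"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": counts.columns,
                "condition": ["probe"] * 3 + ["control"] * 3,
                "replicate": ["R1", "R2", "R3"] * 2,
            }
        )
        return FeatureEnrichment(counts, meta)

    def test_volcano_top_hits_are_enriched(self, rng):
        model = self.make_model(rng, effect_rows=50, n=500)
        res = model.fit()
        df = volcano_table(res)
        assert len(df) == len(model.counts)
        top = df.head(20)
        frac_true = np.mean([int(p[1:]) < 50 for p in top["protein_id"]])
        assert frac_true >= 0.95
        assert (top[top["protein_id"].map(lambda p: int(p[1:]) < 50)]["log2FC"]
                > 1.0).all()

    def test_summary_mentions_fit_dimensions(self, rng):
        res = self.make_model(rng).fit()
        text = res.summary()
        assert "proteins tested" in text and "prior df" in text

    def test_unknown_condition_rejected(self, rng):
        model = self.make_model(rng)
        meta = model.metadata.reset_index()
        meta.loc[0, "condition"] = "mystery"
        with pytest.raises(ValueError):
            FeatureEnrichment(model.counts, meta)

    def test_null_matrix_type_i_error_near_alpha(self, rng):
        hits = []
        for _ in range(40):
            res = self.make_model(rng, effect_rows=0, n=300).fit()
            hits.append((res.p_values < 0.05).mean())
        assert 0.02 <= np.mean(hits) <= 0.08


@pytest.mark.parametrize("d0_source", ["finite", "infinite"])
def test_matches_limma_voom_reference(rng, d0_source, tmp_path):
    """Cross-check against the Bioconductor reference implementation."""
    if d0_source == "finite":
        mu = rng.uniform(5, 500, size=100)[:, None]
        counts = nb_counts(rng, mu, 0.4, (100, 6))
    else:
        counts = nb_counts(rng, 50.0, 0.2, (60, 6))
    counts_file = tmp_path / "counts.txt"
    out_file = tmp_path / "limma.txt"
    np.savetxt(counts_file, counts, fmt="%d", delimiter="\t")
    r_code = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        c <- as.matrix(read.table("{counts_file}"))
        design <- cbind(1, c(1,1,1,0,0,0))
        v <- voom(c, design, span=0.5)
        fit <- eBayes(lmFit(v, design))
        out <- data.frame(coef=fit$coefficients[,2], t=fit$t[,2],
                          p=fit$p.value[,2])
        write.table(out, "{out_file}", sep="\\t", quote=FALSE)
        """
    )
    proc = subprocess.run(
        ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
    )
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(out_file, sep="\t")
    vt = voom(counts, DESIGN)
    mf = moderated_t(vt, DESIGN)
    assert np.allclose(mf.coef, ref["coef"], atol=2e-3)
    assert np.allclose(mf.t, ref["t"], atol=2e-2)
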