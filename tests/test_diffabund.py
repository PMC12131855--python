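"""Linear models, empirical-Bayes moderation, BH FDR, aggregation.

The moderated-t machinery is cross-checked against the Bioconductor limma
implementation (via Rscript) on a small fixture — the R package is the
independent oracle, never the implementation.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import glycardio as gc
from glycardio.diffabund import (
    adjust_bh,
    build_design,
    composition_differential,
    differential_table,
    empirical_bayes_moderation,
    fit_linear_models,
)
from glycardio import synthetic_data as sd


def bh_brute_force(p):
    """Literal step-up definition: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        q[i] = min(min(m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]), 1.0)
    return q


# -- design & OLS -----------------------------------------------------------

def test_design_matrix(toy_metadata):
    X = build_design(toy_metadata, ["age", "sex", "hypertension"])
    assert list(X.columns) == ["intercept", "group", "age", "sex_M",
                               "hypertension"]
    with pytest.raises(ValueError, match="collinear"):
        meta = toy_metadata.copy()
        meta["dup"] = (meta["group"] == "positive").astype(float)
        build_design(meta, ["dup"])
    with pytest.raises(ValueError):
        build_design(toy_metadata, ["missing_cov"])


def test_group_coefficient_is_mean_difference(toy_metadata):
    Y = pd.DataFrame([[3.0] * 6 + [5.0] * 6, [1.0] * 6 + [0.5] * 6],
                     index=["g1", "g2"], columns=toy_metadata.index)
    fits = fit_linear_models(Y, build_design(toy_metadata))
    np.testing.assert_allclose(fits.coef, [2.0, -0.5], atol=1e-12)


def test_orthogonal_covariate_leaves_group_coef(toy_metadata, rng):
    Y = pd.DataFrame(rng.normal(size=(10, 12)), columns=toy_metadata.index)
    meta = toy_metadata.copy()
    cov = rng.normal(size=12)
    group = (meta["group"] == "positive").astype(float).to_numpy()
    gc_ = group - group.mean()
    meta["orth"] = cov - np.dot(cov, gc_) / np.dot(gc_, gc_) * gc_ - (
        cov.mean() - 0)  # orthogonal to both intercept and group
    meta["orth"] -= meta["orth"].mean()
    f0 = fit_linear_models(Y, build_design(meta))
    f1 = fit_linear_models(Y, build_design(meta, ["orth"]))
    np.testing.assert_allclose(f0.coef, f1.coef, atol=1e-10)


def test_fit_requires_more_samples_than_predictors(toy_metadata):
    Y = pd.DataFrame(np.ones((2, 12)), columns=toy_metadata.index)
    X = build_design(toy_metadata)
    with pytest.raises(ValueError):
        fit_linear_models(Y.iloc[:, :2], X.iloc[:2])


# -- moderation -------------------------------------------------------------

def _toy_fits(rng, m=60, n=12, equal_var=False):
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": ["negative"] * (n // 2) + ["positive"] * (n // 2),
    }).set_index("sample_id", drop=False)
    scale = 1.0 if equal_var else rng.uniform(0.5, 2.0, size=(m, 1))
    Y = pd.DataFrame(rng.normal(0, scale, size=(m, n)), columns=meta.index)
    return fit_linear_models(Y, build_design(meta))


def test_prior_df_zero_recovers_ordinary_t(rng):
    fits = _toy_fits(rng)
    mod = empirical_bayes_moderation(fits, prior_df=0.0)
    np.testing.assert_allclose(mod.t, fits.t_ordinary, atol=1e-12)
    p_ref = 2 * stats.t.sf(np.abs(fits.t_ordinary), fits.df_residual)
    np.testing.assert_allclose(mod.p, p_ref, atol=1e-12)


def test_equal_variances_give_ordinary_t_ratios(rng):
    fits = _toy_fits(rng, equal_var=True)
    fits.sigma2[:] = 1.3                      # literally identical s^2
    fits.se[:] = np.sqrt(1.3) * fits.stdev_unscaled
    mod = empirical_bayes_moderation(fits)
    np.testing.assert_allclose(mod.t, fits.t_ordinary, atol=1e-10)
    assert np.isinf(mod.prior_df)


def test_infinite_prior_pools_all_variances(rng):
    fits = _toy_fits(rng)
    mod = empirical_bayes_moderation(fits, prior_df=np.inf)
    np.testing.assert_allclose(mod.posterior_var, mod.prior_var)


def test_posterior_variance_is_convex_combination(rng):
    fits = _toy_fits(rng)
    mod = empirical_bayes_moderation(fits)
    lo = np.minimum(fits.sigma2, mod.prior_var)
    hi = np.maximum(fits.sigma2, mod.prior_var)
    assert ((mod.posterior_var >= lo - 1e-12)
            & (mod.posterior_var <= hi + 1e-12)).all()
    assert (mod.q >= mod.p - 1e-15).all()


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_moderated_t_matches_limma(tmp_path, rng):
    """Independent oracle: Bioconductor limma lmFit/eBayes."""
    fits = _toy_fits(rng, m=40)
    meta_groups = [0] * 6 + [1] * 6
    Y = pd.DataFrame(
        rng.normal(0, rng.uniform(0.5, 2, size=(40, 1)), size=(40, 12)))
    Y.index = [f"g{i}" for i in range(40)]
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(12)],
        "group": ["negative" if g == 0 else "positive" for g in meta_groups],
    }).set_index("sample_id", drop=False)
    Y.columns = meta.index
    mod = empirical_bayes_moderation(
        fit_linear_models(Y, build_design(meta)))
    Y.to_csv(tmp_path / "y.csv")
    script = f"""
    suppressMessages(library(limma))
    Y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1))
    design <- cbind(Intercept=1, group=c({",".join(map(str, meta_groups))}))
    fit <- eBayes(lmFit(Y, design))
    out <- data.frame(t=fit$t[,"group"], p=fit$p.value[,"group"],
                      d0=fit$df.prior, s02=fit$s2.prior)
    write.csv(out, "{tmp_path}/limma.csv")
    """
    (tmp_path / "run.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                   capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
    assert mod.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert mod.prior_var == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
    np.testing.assert_allclose(mod.t, ref["t"].values, atol=1e-10)
    np.testing.assert_allclose(mod.p, ref["p"].values, atol=1e-12)


# -- BH ---------------------------------------------------------------------

def test_bh_step_up_hand_example():
    np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    assert adjust_bh([0.42])[0] == pytest.approx(0.42)
    np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_bh([0.5, 1.5])
    with pytest.raises(ValueError):
        adjust_bh([-0.1])


def test_bh_matches_brute_force_oracle(rng):
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 30))
        np.testing.assert_allclose(adjust_bh(p), bh_brute_force(p), atol=1e-12)


def test_bh_is_order_preserving(rng):
    p = rng.uniform(size=50)
    q = adjust_bh(p)
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-15).all()


# -- result tables ----------------------------------------------------------

def test_differential_table_flags_and_order(rng):
    fits = _toy_fits(rng)
    mod = empirical_bayes_moderation(fits)
    tab = differential_table(mod, {g: "complex-bi" for g in mod.ids})
    assert (tab["p"].diff().dropna() >= 0).all()
    assert tab["significant_p"].equals(tab["p"] < 0.05)
    none = differential_table(mod, q_threshold=0.0)
    assert not none["significant_q"].any()


def test_composition_differential_cancellation():
    # isomers move +5 and -5 relative-abundance units in equal measure
    rel = pd.DataFrame({
        "n1": [10.0, 10.0, 5.0], "n2": [10.0, 10.0, 5.0],
        "p1": [15.0, 5.0, 5.0], "p2": [15.0, 5.0, 5.0],
    }, index=["iso_up", "iso_down", "other"])
    groups = pd.Series({"n1": "negative", "n2": "negative",
                        "p1": "positive", "p2": "positive"})
    comp_of = {"iso_up": "H5N4", "iso_down": "H5N4", "other": "H3N2"}
    out = composition_differential(rel, comp_of, groups).set_index("composition")
    assert out.loc["H5N4", "direction"] == "unchanged"   # +/- isomers cancel
    assert out.loc["H3N2", "log2FC"] == pytest.approx(0.0, abs=1e-12)
    # single-isomer composition log2FC equals the structure-level ratio
    single = composition_differential(
        rel.iloc[[2]], {"other": "H3N2"}, groups).set_index("composition")
    assert single.loc["H3N2", "log2FC"] == pytest.approx(0.0, abs=1e-12)


def test_paucimannose_down_cohort_labels_decreased(tissue_library):
    spec = sd.EffectSpec(seed=33)
    areas, meta, truth = sd.generate_cohort(tissue_library, spec)
    rel = gc.relative_abundance(areas)
    comp_of = dict(zip(tissue_library["glycan_id"],
                       tissue_library["composition"]))
    out = composition_differential(rel, comp_of, meta["group"])
    pauci_comps = set(
        tissue_library.loc[tissue_library["fine_class"] == "paucimannose",
                           "composition"])
    sub = out[out["composition"].isin(pauci_comps)]
    assert len(sub) and (sub["direction"] == "decreased").all()


def test_null_pvalues_are_uniform(tissue_library):
    """No planted effect: pooled p-values pass a KS uniformity check."""
    ps = []
    for seed in range(3):
        spec = sd.EffectSpec(log2fc=0.0, seed=700 + seed)
        areas, meta, _ = sd.generate_cohort(tissue_library, spec)
        logm = gc.median_normalize_log(gc.relative_abundance(areas))
        mod = empirical_bayes_moderation(
            fit_linear_models(logm, build_design(meta)))
        ps.extend(mod.p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01
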