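"""Window construction, design assembly, LRT, heritability, merging and the
scan itself."""

import numpy as np
import pandas as pd
import pytest

from rhmscan import (
    RegionalHeritabilityScan,
    RHMResult,
    ScanConfig,
    VarianceComponents,
    Window,
    build_design,
    lrt_pvalue,
    make_windows,
    manhattan_table,
    merge_regions,
    regional_heritability,
)
from rhmscan.reml import MixedVarianceModel


def _snp_info(positions, chrom="1"):
    return pd.DataFrame(
        {"id": [f"s{p}" for p in positions], "chromosome": chrom, "position": positions}
    )


# --- windows --------------------------------------------------------------


def test_first_windows_follow_k_step_rule():
    info = _snp_info([10_000, 20_000, 60_000, 70_000, 120_000, 130_000])
    ws = make_windows(info, ScanConfig())
    assert (ws[0].start, ws[0].end) == (0, 100_000)
    assert (ws[1].start, ws[1].end) == (50_000, 150_000)


def test_window_enumeration_covers_last_snp():
    info = _snp_info([10_000, 60_000, 110_000, 160_000, 240_000])
    ws = make_windows(info, ScanConfig(min_snps=1))
    starts = sorted({w.start for w in ws})
    assert starts == [0, 50_000, 100_000, 150_000, 200_000]


def test_min_snps_excludes_sparse_windows():
    info = _snp_info([10_000, 300_000, 310_000])
    ws = make_windows(info, ScanConfig(min_snps=2))
    assert all(len(w.snp_ids) >= 2 for w in ws)
    assert not any(w.start == 0 for w in ws)


def test_window_snp_membership_is_half_open():
    info = _snp_info([0, 100_000, 150_000 - 1])
    ws = make_windows(info, ScanConfig(min_snps=1))
    w0 = next(w for w in ws if w.start == 0)
    assert "s0" in w0.snp_ids and "s100000" not in w0.snp_ids


# --- design ---------------------------------------------------------------


def test_design_bookkeeping(planted_sim):
    _, g, records, _ = planted_sim
    d = build_design(records, "GY", list(g.individual_ids))
    assert len(d["y"]) == 98 * 3
    assert d["Z3"].shape == (294, 98)
    np.testing.assert_array_equal(d["Z3"].sum(axis=0), 3.0)
    np.testing.assert_array_equal(d["Z3"].sum(axis=1), 1.0)


def test_design_dropped_plot_consistency(planted_sim):
    _, g, records, _ = planted_sim
    rec = records.drop(index=5).reset_index(drop=True)
    d = build_design(rec, "GY", list(g.individual_ids))
    assert len(d["y"]) == 293
    assert d["Z1"].shape[0] == d["Z3"].shape[0] == 293
    assert d["Z3"].sum() == 293


def test_growth_trait_has_no_covariates(planted_sim):
    _, g, records, _ = planted_sim
    d = build_design(records, "PH", list(g.individual_ids))
    assert d["covariates"] == []
    assert not any(c in d["X"].columns for c in ("plants_per_plot", "kernel_moisture"))


def test_family_without_genotype_errors(planted_sim):
    _, g, records, _ = planted_sim
    rec = records.copy()
    rec.loc[0, "family"] = "GHOST"
    with pytest.raises(ValueError, match="GHOST"):
        build_design(rec, "GY", list(g.individual_ids))


# --- LRT and heritability -------------------------------------------------


def test_lrt_pvalue_reference_values():
    lrt, p = lrt_pvalue(-10.0, -10.0)
    assert (lrt, p) == (0.0, 1.0)
    lrt, p = lrt_pvalue(-4.586, -10.0)  # 2*5.414 = 10.828
    assert p == pytest.approx(0.001, rel=5e-3)
    _, p_chi = lrt_pvalue(-8.0, -10.0, "chi2_1df")
    _, p_mix = lrt_pvalue(-8.0, -10.0, "mixture_50_50")
    assert p_mix == pytest.approx(p_chi / 2, rel=1e-12)


def test_lrt_clipped_at_zero():
    lrt, p = lrt_pvalue(-11.0, -10.0)
    assert lrt == 0.0 and p == 1.0


def test_regional_heritability_arithmetic():
    assert regional_heritability(VarianceComponents(5.0, 0.0, 1.0, 1.0))[0] == 0.0
    h2r, h2u = regional_heritability(VarianceComponents(0.0, 1.0, 1.0, 2.0))
    assert h2r == pytest.approx(0.25) and h2u == pytest.approx(0.25)
    assert regional_heritability(VarianceComponents(0.0, 2.0, 0.0, 0.0))[0] == 1.0
    with pytest.raises(ValueError, match="zero"):
        regional_heritability(VarianceComponents(1.0, 0.0, 0.0, 0.0))


def test_negative_component_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        VarianceComponents(-0.1, 0.0, 0.0, 1.0)


# --- scan behaviour -------------------------------------------------------


@pytest.fixture(scope="module")
def fitted_scan(planted_sim):
    _, g, records, _ = planted_sim
    scan = RegionalHeritabilityScan(g, records, "GY")
    return scan, scan.fit()


def test_scan_localizes_planted_qtl(fitted_scan, planted_sim):
    cfg, *_ = planted_sim
    chrom, w_start, w_end = cfg.qtl_windows[0]
    _, res = fitted_scan
    tab = res.to_frame()
    best = tab.loc[tab["p_value"].idxmin()]
    assert str(best["chromosome"]) == chrom
    assert best["start"] < w_end and best["end"] > w_start
    assert best["p_value"] < 1e-4


def test_scan_lrt_nonnegative_and_h2_bounded(fitted_scan):
    _, res = fitted_scan
    tab = res.to_frame()
    assert (tab["lrt"] >= 0).all()
    assert tab["h2_region"].between(0, 1).all()


def test_null_model_equals_full_model_with_zero_regional_matrix(fitted_scan):
    """Adding a regional component with a zero covariance kernel cannot move
    the REML optimum: logL matches the null fit."""
    scan, res = fitted_scan
    null_ll = res.null_fit.loglik
    y = scan.design["y"]
    X = scan.design["X"].to_numpy(float)
    structures = scan._structures_null()
    with_zero = [structures[0], np.zeros((len(y), len(y))), structures[1], structures[2]]
    fit = MixedVarianceModel(y, X, with_zero).fit()
    assert fit.loglik == pytest.approx(null_ll, abs=1e-4)


def test_scan_determinism(planted_sim):
    _, g, records, _ = planted_sim
    t1 = RegionalHeritabilityScan(g, records, "GY").fit().to_frame()
    t2 = RegionalHeritabilityScan(g, records, "GY").fit().to_frame()
    pd.testing.assert_frame_equal(t1, t2)


def test_permuting_families_destroys_signal(planted_sim):
    cfg, g, records, _ = planted_sim
    chrom, w_start, w_end = cfg.qtl_windows[0]
    scan = RegionalHeritabilityScan(g, records, "GY")
    null = scan.fit_null()
    target = next(w for w in scan.windows if w.start == w_start and w.chromosome == chrom)
    full = scan.fit_window(target, null_res=null)
    _, p_planted = lrt_pvalue(full.loglik, null.loglik)

    rng = np.random.default_rng(0)
    fam_map = dict(zip(sorted(records["family"].unique()),
                       rng.permutation(sorted(records["family"].unique()))))
    perm = records.assign(family=records["family"].map(fam_map))
    scan_p = RegionalHeritabilityScan(g, perm, "GY")
    null_p = scan_p.fit_null()
    full_p = scan_p.fit_window(target, null_res=null_p)
    _, p_perm = lrt_pvalue(full_p.loglik, null_p.loglik)
    assert p_planted < 1e-5
    assert p_perm > 1e-3 * 10  # signal gone after permutation


# --- merging and reporting ------------------------------------------------


def _result(chrom, start, end, p, snps=("a", "b"), h2=0.2):
    return RHMResult(
        window=Window(chrom, start, end, tuple(f"{chrom}:{start}:{s}" for s in snps)),
        trait="GY", environment="ENV1",
        components=VarianceComponents(0.0, 1.0, 1.0, 2.0),
        logL_full=0.0, logL_null=0.0, lrt=0.0, p_value=p,
        h2_region=h2, h2_polygenic=0.2, converged=True,
    )


def test_merge_overlapping_windows_into_one_region():
    rs = [_result("1", 0, 100_000, 1e-4), _result("1", 50_000, 150_000, 1e-5)]
    regions = merge_regions(rs, alpha=0.001)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (0, 150_000)
    assert regions[0].n_snps == 4
    assert regions[0].peak_neglog10p == pytest.approx(5.0)


def test_merge_disjoint_windows_stay_separate():
    rs = [_result("1", 0, 100_000, 1e-4), _result("1", 200_000, 300_000, 1e-4)]
    assert len(merge_regions(rs, alpha=0.001)) == 2


def test_merge_no_significant_windows_empty():
    rs = [_result("1", 0, 100_000, 0.5)]
    assert merge_regions(rs, alpha=0.001) == []


def test_merge_matches_bruteforce_interval_union():
    rng = np.random.default_rng(7)
    for _ in range(20):
        starts = np.sort(rng.choice(np.arange(0, 40) * 50_000, size=8, replace=False))
        ps = rng.choice([1e-4, 0.5], size=8)
        rs = [_result("1", int(s), int(s) + 100_000, p) for s, p in zip(starts, ps)]
        regions = merge_regions(rs, alpha=0.001)
        # brute force: mark covered bp of significant windows, count runs
        sig = [(r.window.start, r.window.end) for r in rs if r.p_value <= 0.001]
        covered = np.zeros(45 * 50_000 // 1000, dtype=bool)
        for s, e in sig:
            covered[s // 1000 : e // 1000] = True
        n_runs = int(np.diff(np.concatenate([[0], covered.astype(int)])).clip(0).sum())
        assert len(regions) == n_runs


def test_manhattan_flags_and_conservation():
    rs = [
        _result("1", 0, 100_000, 1e-3),
        _result("1", 50_000, 150_000, 1.0),
        _result("2", 0, 100_000, 0.2),
    ]
    tab = manhattan_table(rs, alpha=1e-3)
    assert len(tab) == 3
    row = tab[(tab.chromosome == "1") & (tab.start == 0)].iloc[0]
    assert row["neglog10_p"] == pytest.approx(3.0)
    assert bool(row["significant"])  # p = alpha counts as significant
    assert not tab[(tab.start == 50_000)]["significant"].iloc[0]
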