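"""Estimator correctness: closed forms, a brute-force oracle, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

import tailoseq as ts
from tailoseq.errors import EmptyAssayError, PairingError
from tailoseq.fitness import SIGMA0


def _pool(n_genes, strains_per_gene=1):
    import itertools

    kmers = ("".join(k) for k in itertools.product("ACGT", repeat=6))
    rows = [
        {"barcode": next(kmers), "locus_tag": f"gene{g:03d}", "gene_fraction": 0.5}
        for g in range(n_genes)
        for _ in range(strains_per_gene)
    ]
    return pd.DataFrame(rows)


def _counts(pool, value):
    return pd.Series(value, index=pd.Index(pool["barcode"], name="barcode"))


def test_flat_counts_give_zero_fitness():
    pool = _pool(7)
    strains = ts.strain_fitness(pool, _counts(pool, 15), _counts(pool, 15))
    assert np.allclose(strains["r_raw"], 0)
    assert np.allclose(strains["f_s"], 0)


def test_single_shifted_strain_closed_form():
    """n0=3 -> n_after=63 with pseudocount 1 gives log2(64/4) = 4."""
    pool = _pool(7)
    n0 = _counts(pool, 15)
    after = _counts(pool, 15)
    bc = pool["barcode"].iloc[0]
    n0[bc], after[bc] = 3, 63
    strains = ts.strain_fitness(pool, n0, after)
    # 6 flat genes + 1 shifted: median of preliminary gene fitness is 0
    assert strains.loc[strains["barcode"] == bc, "f_s"].iloc[0] == pytest.approx(4.0)


def test_gene_fitness_trivial_aggregations():
    strains = pd.DataFrame(
        {
            "barcode": ["AAAA", "AAAC", "AAAG"],
            "locus_tag": ["gA", "gB", "gB"],
            "n0": [100.0, 100.0, 100.0],
            "n_after": [100.0, 100.0, 100.0],
            "r_raw": [1.0, 2.0, 4.0],
            "f_s": [1.0, 2.0, 4.0],
            "w_s": [1.0, 3.0, 3.0],
            "used": [True, True, True],
        }
    )
    genes = ts.gene_fitness(strains, total0=300, total_after=300)
    assert genes.loc["gA", "f"] == pytest.approx(1.0)  # single strain: f_g = f_s
    assert genes.loc["gB", "f"] == pytest.approx(3.0)  # equal weights: mean of 2 and 4


def test_gene_fitness_matches_bruteforce_oracle():
    """Random instances vs a naive weighted mean computed from scratch."""
    rng = np.random.default_rng(11)
    for trial in range(5):
        n = 50
        genes = [f"g{i}" for i in rng.integers(0, 20, size=n)]
        strains = pd.DataFrame(
            {
                "barcode": [f"B{i}" for i in range(n)],
                "locus_tag": genes,
                "n0": rng.integers(3, 500, size=n).astype(float),
                "n_after": rng.integers(0, 500, size=n).astype(float),
                "r_raw": rng.normal(size=n),
                "f_s": rng.normal(size=n),
                "w_s": rng.uniform(0.1, 10, size=n),
                "used": True,
            }
        )
        result = ts.gene_fitness(strains, total0=1.0, total_after=1.0)
        for gene in set(genes):
            d = strains[strains["locus_tag"] == gene]
            num = sum(w * f for w, f in zip(d["w_s"], d["f_s"]))
            den = sum(d["w_s"])
            assert abs(result.loc[gene, "f"] - num / den) < 1e-12


def test_gene_fitness_bounded_by_strain_fitness():
    rng = np.random.default_rng(5)
    n = 30
    strains = pd.DataFrame(
        {
            "barcode": [f"B{i}" for i in range(n)],
            "locus_tag": [f"g{i % 6}" for i in range(n)],
            "n0": 100.0,
            "n_after": 100.0,
            "r_raw": 0.0,
            "f_s": rng.normal(size=n),
            "w_s": rng.uniform(0.1, 5, size=n),
            "used": True,
        }
    )
    genes = ts.gene_fitness(strains, 1.0, 1.0)
    for gene, d in strains.groupby("locus_tag"):
        assert d["f_s"].min() - 1e-12 <= genes.loc[gene, "f"] <= d["f_s"].max() + 1e-12


def test_t_statistic_closed_forms():
    assert ts.t_statistic(0.0, 0.37) == 0.0
    # sigma0^2 = 0.01: V=0.24 -> denominator sqrt(0.25)
    assert ts.t_statistic(5.0, 0.24) == pytest.approx(10.0)


def test_t_magnitude_decreases_with_variance():
    rng = np.random.default_rng(2)
    for _ in range(50):
        f = rng.normal(scale=3)
        v1, v2 = sorted(rng.uniform(0.0, 4.0, size=2))
        assert abs(ts.t_statistic(f, v2)) <= abs(ts.t_statistic(f, v1)) + 1e-15


def test_per_sample_median_normalization_is_exact():
    """Median of preliminary gene fitness is 0 for odd gene counts."""
    cfg = ts.SimulationConfig(n_genes=101, depth_time0=30_000, depth_after=30_000, seed=9)
    pool, time0, truth = ts.generate_library(cfg)
    treated = ts.simulate_selection(time0, truth, "Max", cfg)
    strains = ts.strain_fitness(pool, time0, treated)
    u = strains[strains["used"]]
    prelim = u.groupby("locus_tag").apply(
        lambda d: np.average(d["f_s"], weights=d["w_s"]), include_groups=False
    )
    assert abs(np.median(prelim)) < 1e-12


def test_depth_approximate_invariance():
    cfg = ts.SimulationConfig(n_genes=60, depth_time0=40_000, depth_after=40_000, seed=6)
    pool, time0, truth = ts.generate_library(cfg)
    treated = ts.simulate_selection(time0, truth, "Max", cfg)
    g1 = ts.gene_fitness(ts.strain_fitness(pool, time0, treated), time0.sum(), treated.sum())
    g2 = ts.gene_fitness(ts.strain_fitness(pool, 2 * time0, 2 * treated), 2 * time0.sum(), 2 * treated.sum())
    common = g1.index.intersection(g2.index)
    assert (g1.loc[common, "f"] - g2.loc[common, "f"]).abs().max() < 0.1


def test_average_replicates_closed_forms():
    rec = pd.DataFrame(
        {"f": [6.0], "t": [3.0], "V_g": [0.2], "n_strains": [2],
         "reads_before": [10.0], "reads_after": [20.0]},
        index=pd.Index(["gA"], name="locus_tag"),
    )
    rec2 = rec.copy()
    rec2["f"] = 8.0
    avg = ts.average_replicates([rec, rec2])
    assert avg.loc["gA", "f"] == pytest.approx(7.0)
    # identical replicates: f unchanged, |t| grows by sqrt(R)
    t_single = rec["f"].iloc[0] / math.sqrt(rec["V_g"].iloc[0] + SIGMA0**2)
    same = ts.average_replicates([rec, rec.copy()])
    assert same.loc["gA", "f"] == pytest.approx(6.0)
    assert same.loc["gA", "t"] == pytest.approx(t_single * math.sqrt(2))
    single = ts.average_replicates([rec])
    assert single.loc["gA", "f"] == 6.0


def test_recovery_of_moderate_spiked_effect():
    """phi=8 spiked gene recovered within [6.5, 9.5] across seeds."""
    for seed in range(1, 6):
        cfg = ts.SimulationConfig(
            n_genes=200, depth_time0=200_000, depth_after=200_000,
            receptor_genes=("g0007",), phi_receptor_range=(8.0, 8.0), seed=seed,
        )
        pool, time0, truth = ts.generate_library(cfg)
        treated = ts.simulate_selection(time0, truth, "Max", cfg)
        genes = ts.gene_fitness(ts.strain_fitness(pool, time0, treated), time0.sum(), treated.sum())
        assert 6.5 <= genes.loc["g0007", "f"] <= 9.5


def test_empty_assay_and_pairing_errors(small_assay):
    pool = _pool(3)
    pool["gene_fraction"] = 0.95  # everything outside the central window
    with pytest.raises(EmptyAssayError):
        ts.strain_fitness(pool, _counts(pool, 10), _counts(pool, 10))

    _, pool2, counts, samples, _ = small_assay
    broken = samples.copy()
    broken.loc[~broken["is_time0"], "time0_sample"] = "nonexistent"
    with pytest.raises(PairingError):
        ts.fit_assay(pool2, counts, broken)
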