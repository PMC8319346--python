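import pytest

import tailoseq as ts


@pytest.fixture(scope="session")
def small_assay():
    """A 50-gene duplicate assay with one strong receptor gene (phi=16)."""
    cfg = ts.SimulationConfig(
        n_genes=50,
        depth_time0=50_000,
        depth_after=50_000,
        receptor_genes=("g0005",),
        seed=1,
    )
    pool, counts, samples, truth = ts.generate_assay(cfg)
    return cfg, pool, counts, samples, truth


@pytest.fixture(scope="session")
def strain_panel():
    """60-strain, 8-clade panel with phenotype = receptor-orthogroup rule."""
    cfg = ts.PanelConfig(n_strains=60, n_clades=8, seed=7)
    genomes, sens, truth = ts.generate_strain_panel(cfg)
    return cfg, genomes, sens, truth


@pytest.fixture(scope="session")
def panel_partition(strain_panel):
    """Zero-height OSA-content clusters of the panel."""
    _, genomes, _, _ = strain_panel
    sets = {g.strain: ts.osa_orthogroup_set(ts.delineate_all(g)["OSA"]) for g in genomes}
    dist = ts.distance_matrix(sets)
    tree = ts.single_linkage(dist)
    return ts.cut_clusters(tree, 0.0)
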