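import numpy as np
import pandas as pd
import pytest

from metscreen import ScreenDataset, ScreenSimConfig, simulate_screen


def make_screen_table(records):
    """records: (hairpin, gene, line, group, timepoint, replicate, value)."""
    return pd.DataFrame(
        records,
        columns=[
            "hairpin_id",
            "gene_id",
            "line_id",
            "group",
            "timepoint",
            "replicate",
            "log2_abundance",
        ],
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two genes, two lines, hand-written values for closed-form checks."""
    rows = []
    # gA/sh1 in pri0: constant 8; in met0: exact line 10 - t
    for t in (0, 1, 2):
        rows.append(("gA_sh1", "gA", "pri0", "primary", t, 0, 8.0))
        rows.append(("gA_sh1", "gA", "met0", "metastatic", t, 0, 10.0 - t))
    # gA/sh2 in pri0: noisy-ish fixed values for the OLS oracle
    for t, v in zip((0, 1, 2), (10.1, 8.9, 8.1)):
        rows.append(("gA_sh2", "gA", "pri0", "primary", t, 0, v))
        rows.append(("gA_sh2", "gA", "met0", "metastatic", t, 0, 9.0))
    # gB only in pri0
    for t in (0, 1, 2):
        rows.append(("gB_sh1", "gB", "pri0", "primary", t, 0, 7.0 - 2.0 * t))
    return ScreenDataset(make_screen_table(rows))


@pytest.fixture(scope="session")
def noiseless_screen():
    """Seeded zero-noise screen with one fully penetrant differential gene."""
    cfg = ScreenSimConfig(
        n_genes=12,
        noise_sd=0.0,
        differential_gene_ids=("g0004",),
        frac_metastatic_dependent=1.0,
        essential_gene_frac=0.25,
        seed=11,
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def noisy_screen():
    """Seeded sigma=0.3 screen under the global null for the interaction."""
    return simulate_screen(
        ScreenSimConfig(n_genes=40, noise_sd=0.3, essential_gene_frac=0.1, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
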