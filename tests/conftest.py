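import numpy as np
import pandas as pd
import pytest

from cnaloh import PairedExome, SimConfig, simulate_exome


@pytest.fixture
def exon_db_file(tmp_path):
    path = tmp_path / "exons.bed"
    path.write_text(
        "chr1\t100\t200\tGENE1_ex1\n"
        "chr1\t300\t350\tGENE1_ex2\n"
        "chr2\t50\t150\tGENE2_ex1\n"
    )
    return str(path)


@pytest.fixture
def flat_pair():
    """A 3-chromosome paired exome with identical flat coverage."""
    rows = []
    for chrom in ("1", "2", "3"):
        for i in range(60):
            rows.append((f"{chrom}_ex{i}", chrom, i * 1000, i * 1000 + 150,
                         100.0, 0.0))
    df = pd.DataFrame(rows, columns=["exon_label", "chrom", "start", "end",
                                     "mean_cov", "cov_sd"])
    return df.copy(), df.copy()


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic simulated exome with a handful of 10-exon events."""
    cfg = SimConfig(n_exons={"1": 1000, "2": 1000}, rnd_cn=0.1, p_cn1=1.8e-3,
                    event_size=10, min_gap=30, seed=42)
    return simulate_exome(cfg)


@pytest.fixture(scope="session")
def small_sim_results(small_sim):
    from cnaloh import resolve_preset
    pe = PairedExome.from_tables(small_sim.case_table,
                                 small_sim.control_table,
                                 small_sim.het_table)
    return pe, pe.fit(resolve_preset("small"))
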