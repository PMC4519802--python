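import numpy as np
import pandas as pd
import pytest

import mirualb as m


@pytest.fixture(scope="session")
def table1():
    return m.load_table1_fixture()


@pytest.fixture(scope="session")
def table2_models():
    return m.load_table2_models()


@pytest.fixture()
def small_cohort():
    """A 30-species synthetic cohort with the study's group structure."""
    cfg = m.SynthConfig(seed=11, n_species=30)
    cq, samples, truth = m.generate(cfg)
    return cfg, cq, samples, truth


def _demo_path(name):
    from importlib import resources

    return resources.files("mirualb.data").joinpath("demo").joinpath(name)


@pytest.fixture(scope="session")
def target_sources():
    """Three packaged prediction sources over 20 miRNAs x ~100 genes."""
    from mirualb.targets import read_target_table

    tables = {}
    for src in ("mirandalike", "targetscanlike", "mirdblike"):
        name, tbl = read_target_table(_demo_path(f"targets_{src}.tsv"))
        tables[name] = tbl
    return tables


@pytest.fixture(scope="session")
def renal_list():
    from mirualb.targets import read_gene_list

    return read_gene_list(_demo_path("renal_genes.txt"))


@pytest.fixture(scope="session")
def pathway_db():
    from mirualb.targets import read_gmt

    return read_gmt(_demo_path("pathways.gmt"))


def sample_frame(groups, sexes):
    """Minimal SampleTable from parallel group/sex lists."""
    rows = [
        {
            "id": f"P{i + 1}",
            "group": g,
            "sex": s,
            "age": 30.0 + i,
            "hba1c": 8.0,
            "duration": 20.0 + i,
            "cycle": 2,
            "cad": False, "stroke": False, "pvd": False,
            "neuropathy": False, "retinopathy": False, "htn": False,
        }
        for i, (g, s) in enumerate(zip(groups, sexes))
    ]
    return m.SampleTable(pd.DataFrame(rows))
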