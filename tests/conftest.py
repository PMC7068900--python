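import numpy as np
import pandas as pd
import pytest

from linkinv.genomics_io import GenotypePanel


def build_panel(rows, genotypes, samples, colony_of, role_of=None,
                phased=False) -> GenotypePanel:
    """Construct a panel from (chrom, pos, ref, alt[, qd, fs, ranksum]) rows."""
    cols = ["chrom", "pos", "ref", "alt", "qd", "fs", "ranksum"]
    full = [tuple(r) + (20.0, 1.0, 0.0)[:7 - len(r)] for r in rows]
    sites = pd.DataFrame(full, columns=cols[:len(full[0])])
    for c in ("qd", "fs", "ranksum"):
        if c not in sites:
            sites[c] = np.float32(20.0 if c == "qd" else 0.0)
        sites[c] = sites[c].astype(np.float32)
    return GenotypePanel(sites=sites,
                         genotypes=np.asarray(genotypes, dtype=np.int8),
                         samples=list(samples), colony_of=dict(colony_of),
                         role_of=dict(role_of or {}), phased=phased)


@pytest.fixture
def two_colony_panel():
    """4 diploids in 2 colonies, 3 sites; colony B fixed alt at site 2."""
    rows = [("1", 100, "A", "C"), ("1", 200, "G", "T"), ("2", 50, "T", "A")]
    g = np.zeros((3, 4, 2), dtype=np.int8)
    g[1, 2:, :] = 1          # site 2 fixed alt in colony B
    g[0, 1, 1] = 1           # one het in colony A at site 1
    samples = ["a1", "a2", "b1", "b2"]
    colony_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return build_panel(rows, g, samples, colony_of,
                       {"A": "Aaa", "B": "Aaf"})


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study, shared across tests (read-only)."""
    from linkinv.simulate import SimConfig, simulate_all

    return simulate_all(SimConfig(seed=7))
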