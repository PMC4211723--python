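import numpy as np
import pytest

from hetmig.genotypes import GenotypeTable


def table_from_calls(rows, loci, group=None):
    """Build a GenotypeTable from [(id, [(a, b) | None, ...]), ...]."""
    ids = [r[0] for r in rows]
    calls = np.empty((len(rows), len(loci), 2), dtype=object)
    for i, (_, genos) in enumerate(rows):
        for j, call in enumerate(genos):
            if call is None:
                calls[i, j, 0] = calls[i, j, 1] = None
            else:
                calls[i, j, 0], calls[i, j, 1] = call
    return GenotypeTable(ids, loci, calls, group)


@pytest.fixture(scope="session")
def default_sim():
    """Study-shaped synthetic dataset (134 x 17) shared across tests."""
    import hetmig as hm

    cfg = hm.SimConfig(seed=42)
    table, truth = hm.simulate_genotypes(cfg)
    return cfg, table, truth


@pytest.fixture
def hwe_table():
    """One biallelic locus at exact Hardy-Weinberg proportions (25/50/25)."""
    rows = []
    k = 0
    for geno, count in [(("A", "A"), 25), (("A", "B"), 50), (("B", "B"), 25)]:
        for _ in range(count):
            k += 1
            rows.append((f"i{k}", [geno]))
    return table_from_calls(rows, ["L1"])
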