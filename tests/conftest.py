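import numpy as np
import pandas as pd
import pytest

from ubipan.simulate import CohortSpec, simulate_cohort
from ubipan.types import AbundanceMatrix


def make_matrix(values: np.ndarray, paired: bool = True,
                cohort: str = "X") -> AbundanceMatrix:
    """Wrap a (features x 2n) array as a paired tumor/normal matrix:
    first half of columns tumor, second half their paired normals."""
    m, two_n = values.shape
    n = two_n // 2
    cols = ([f"{cohort}T{i:03d}" for i in range(n)]
            + [f"{cohort}N{i:03d}" for i in range(n)])
    pair = [f"{cohort}P{i:03d}" for i in range(n)] * 2 if paired \
        else [np.nan] * two_n
    design = pd.DataFrame({
        "sample_id": cols, "cohort": cohort,
        "condition": ["tumor"] * n + ["normal"] * n, "pair_id": pair,
    }).set_index("sample_id")
    frame = pd.DataFrame(values, index=[f"F{i:04d}" for i in range(m)],
                         columns=cols)
    return AbundanceMatrix(frame, design)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared across tests (read-only)."""
    spec = CohortSpec(n_pairs=20, n_proteins=200, n_e3=20, n_dub=8,
                      esi_per_e3=4, frac_degradative=0.1, effect_log2fc=2.0,
                      missing_rate=0.05, seed=42)
    prot, rna, sites, catalog, esi_net, truth = simulate_cohort(spec)
    return {"spec": spec, "proteome": prot, "rna": rna, "sites": sites,
            "catalog": catalog, "esi": esi_net, "truth": truth}
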