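import numpy as np
import pandas as pd
import pytest

from gsem_cortex.ldsc_engine import multivariable_ldsc
from gsem_cortex.synthetic_data import GenerativeSpec, simulate_sumstats

NAMES = list("ABCDEF")


def two_factor_population(loading_sets=((0.7, 0.6, 0.5), (0.65, 0.55, 0.45)), phi12=0.4):
    """Population correlation-metric matrices of a 6-indicator 2-factor model."""
    lam = np.zeros((6, 2))
    lam[:3, 0] = loading_sets[0]
    lam[3:, 1] = loading_sets[1]
    phi = np.array([[1.0, phi12], [phi12, 1.0]])
    common = lam @ phi @ lam.T
    theta = np.diag(1.0 - np.diag(common))
    return lam, phi, common + theta


@pytest.fixture(scope="session")
def pop_model():
    lam, phi, S = two_factor_population()
    return {"lam": lam, "phi": phi, "S": S, "names": NAMES,
            "V": np.eye(21) * 1e-6,
            "assignment": {n: ("F1" if i < 3 else "F2") for i, n in enumerate(NAMES)}}


@pytest.fixture(scope="session")
def small_study():
    """One simulated two-factor study with its LDSC (S, V) — shared across tests."""
    spec = GenerativeSpec.two_factor(seed=3)
    study = simulate_sumstats(spec)
    pair = multivariable_ldsc(study.sumstats, study.ld, m_ref=spec.M)
    return {"spec": spec, "study": study, "pair": pair}


@pytest.fixture()
def toy_sumstats():
    """Five-variant raw table exercising each munge filter branch."""
    raw = pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "A1": ["A", "A", "C", "G", "A"],
            "A2": ["G", "T", "T", "A", "C"],
            "Z": [1.0, 0.5, 2.0, -0.3, 1.2],
            "N": [1000.0] * 5,
            "MAF": [0.3, 0.2, 0.25, 0.4, 0.005],
        }
    )
    ref = pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "A1": ["A", "A", "T", "G", "A"],
            "A2": ["G", "T", "C", "A", "C"],
        }
    )
    return raw, ref
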