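import numpy as np
import pandas as pd
import pytest

from tmtcycle import syndata as sd
from tmtcycle import normalize as nm


@pytest.fixture(scope="session")
def small_params():
    return sd.SimParams(
        n_proteins=300,
        n_genes=40,
        frac_dependent=0.2,
        frac_rescued_given_dependent=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def bundle(small_params):
    return sd.simulate_all(small_params)


@pytest.fixture(scope="session")
def normalized(bundle):
    filtered = nm.filter_features(bundle["matrix"])
    return nm.reference_normalize(filtered, bundle["design"])


@pytest.fixture
def toy_design():
    """Two plexes, one reference each, 2x2 genotype/feeding with n=2."""
    rows = []
    for p, plex in enumerate(["plex1", "plex2"], start=1):
        rows.append(
            dict(sample=f"REF_{plex}", tissue="liver", genotype="POOL",
                 feeding="POOL", plex=plex, channel="ch01",
                 is_reference=True, replicate=0)
        )
    i = 0
    for genotype in ("WT", "KO"):
        for feeding in ("AL", "TRF"):
            for rep in (1, 2):
                plex = "plex1" if i % 2 == 0 else "plex2"
                rows.append(
                    dict(sample=f"{genotype}_{feeding}_{rep}", tissue="liver",
                         genotype=genotype, feeding=feeding, plex=plex,
                         channel=f"ch{2 + i // 2:02d}", is_reference=False,
                         replicate=rep)
                )
                i += 1
    return pd.DataFrame(rows)


def make_matrix(values: np.ndarray, samples, scale="raw", meta_extra=None):
    """Build an AbundanceMatrix from a plain array for tests."""
    from tmtcycle.io import AbundanceMatrix

    n = values.shape[0]
    ids = pd.Index([f"P{i:03d}" for i in range(n)], name="protein_id")
    meta = pd.DataFrame(
        {
            "gene": [f"G{i:03d}" for i in range(n)],
            "n_peptides": 2,
            "flag_contaminant": False,
            "flag_decoy": False,
            "flag_single_oxidized": False,
        },
        index=ids,
    )
    if meta_extra:
        for k, v in meta_extra.items():
            meta[k] = v
    vals = pd.DataFrame(values, index=ids, columns=list(samples))
    return AbundanceMatrix(vals, meta, scale=scale)
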