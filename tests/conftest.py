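import numpy as np
import pandas as pd
import pytest

from dompop.io_core import BandMatrix, Dataset, SampleTable


def make_dataset(X, pops, habitats=None, lons=None, lats=None,
                 replicate_of=None, locus_meta=None, locus_ids=None):
    """Assemble a Dataset from a raw matrix and per-individual metadata."""
    X = np.asarray(X)
    n = X.shape[0]
    ids = [f"i{j}" for j in range(n)]
    cols = locus_ids or [f"L{k}" for k in range(X.shape[1])]
    bm = BandMatrix(pd.DataFrame(X, index=ids, columns=cols), locus_meta)
    st = SampleTable(pd.DataFrame({
        "individual_id": ids,
        "population_id": list(pops),
        "habitat": habitats or ["dune"] * n,
        "lon": lons or [4.0] * n,
        "lat": lats or [51.0] * n,
        "replicate_of": replicate_of or [pd.NA] * n,
    }))
    return Dataset(bm, st)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Two moderately differentiated populations of 20, 100 loci."""
    rng = np.random.default_rng(42)
    fa = rng.beta(2, 2, 100)
    fb = np.clip(fa + rng.normal(0, 0.25, 100), 0.02, 0.98)
    X = np.concatenate([(rng.random((20, 100)) < fa).astype(int),
                        (rng.random((20, 100)) < fb).astype(int)])
    return make_dataset(X, ["A"] * 20 + ["B"] * 20,
                        habitats=["dune"] * 20 + ["fen"] * 20,
                        lons=[3.0] * 20 + [5.0] * 20,
                        lats=[50.5] * 20 + [52.0] * 20)
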