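import numpy as np
import pytest

import platsig as ps


@pytest.fixture(scope="session")
def three_sigs() -> ps.SignatureSet:
    return ps.generate_signatures(3, concentration=0.5, seed=17)


@pytest.fixture(scope="session")
def small_cohort() -> ps.CohortData:
    """A compact paired cohort reused across module tests."""
    cfg = ps.SimulationConfig(
        n_patients=8,
        mutations_per_tumor=400,
        strand_bias={"treatment": {"C>A": 3.0}},
        seed=101,
    )
    return ps.generate_paired_cohort(cfg)


@pytest.fixture(scope="session")
def mixture_catalog(three_sigs) -> tuple[ps.MutationCatalog, np.ndarray]:
    """Catalog of multinomial draws from known signature mixtures + truth H."""
    rng = np.random.default_rng(23)
    n_samples, per_sample = 20, 1000
    H = rng.dirichlet([1.0, 1.0, 1.0], size=n_samples).T * per_sample
    V = np.zeros((96, n_samples), dtype=np.int64)
    for s in range(n_samples):
        for k in range(3):
            V[:, s] += rng.multinomial(int(round(H[k, s])), three_sigs.W[:, k])
    catalog = ps.MutationCatalog(
        ps.CHANNELS_96, [f"s{j:02d}" for j in range(n_samples)], V
    )
    return catalog, H


@pytest.fixture()
def tiny_fasta(tmp_path):
    """An indexed two-contig FASTA for reference-context tests."""
    import pyfaidx

    path = tmp_path / "ref.fa"
    path.write_text(">chr1\nACATGGCTAGCTT\n>chr2\nTTGCCA\n")
    return pyfaidx.Fasta(str(path))
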