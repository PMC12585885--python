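import numpy as np
import pytest

import svkaryo as sk
from svkaryo import ancestry as anc


@pytest.fixture(scope="session")
def study():
    """Default study-shaped simulation: 24 chroms, 13 SVs, 185 samples."""
    cfg = sk.default_study_config(seed=1)
    gm, truth = sk.simulate_study(cfg)
    return cfg, gm, truth


@pytest.fixture(scope="session")
def study_pops(study):
    _, gm, truth = study
    grp = truth.ancestry.set_index("sample")["group"]
    return {k: [s for s in gm.samples if grp[s] == k] for k in ("C", "S", "M")}


@pytest.fixture(scope="session")
def truth_profiles(study):
    """Ternary profiles computed from the simulator's true q vectors."""
    _, gm, truth = study
    return anc.classify_profiles(truth.q_matrix(), gm.samples)


@pytest.fixture(scope="session")
def small_collinear():
    """Collinear-only simulation, three lineages, no SVs."""
    cfg = sk.SimConfig(
        n_per_group={"C": 20, "S": 20, "M": 20},
        n_chroms=2, sites_per_chrom=1500, chrom_length_bp=400_000, seed=11,
    )
    gm, truth = sk.simulate_collinear(cfg)
    return cfg, gm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genotypes(rng, n, m, missing_frac=0.0):
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_frac:
        d[rng.uniform(size=d.shape) < missing_frac] = -1
    return d


def make_gm(dosage, chrom="chr1", spacing=100, start=1):
    """Wrap a dosage array into a GenotypeMatrix with evenly spaced sites."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    from svkaryo.matrix import make_site_table

    pos = start + spacing * np.arange(m)
    sites = make_site_table([chrom] * m, pos, ["A"] * m, ["G"] * m)
    return sk.GenotypeMatrix([f"s{i}" for i in range(n)], sites, dosage)
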