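import numpy as np
import pytest

from herdqc.simulate import SimConfig, simulate_herd
from herdqc.types import GenotypeRecord, SnpDef, SnpMap


@pytest.fixture(scope="session")
def tiny_map() -> SnpMap:
    """Nine autosomal panel SNPs plus chrX (PAR + nPAR) and chrY SNPs."""
    snps = [
        SnpDef(f"A{i}", str(i % 3 + 1), 100 + i * 10, in_icbf800=True)
        for i in range(9)
    ]
    snps += [
        SnpDef("X1", "X", 100, is_par=False),
        SnpDef("X2", "X", 200, is_par=False),
        SnpDef("XP", "X", 300, is_par=True),
        SnpDef("Y1", "Y", 100),
    ]
    return SnpMap(snps)


def make_record(snp_map: SnpMap, calls, sample_id="s1", animal_id=None) -> GenotypeRecord:
    calls = np.asarray(calls, dtype=np.int8)
    assert calls.size == len(snp_map)
    return GenotypeRecord(
        sample_id=sample_id, animal_id=animal_id or sample_id, calls=calls
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, fault-free herd: the all-green baseline."""
    cfg = SimConfig(
        seed=11, error_rate=0.0, missing_rate=0.0, parent_misrecording=0.0,
        n_founders_per_breed=20, n_generations=2, n_offspring_per_breed_per_gen=25,
    )
    return simulate_herd(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Realistic herd: 0.2% call error, 0.5% missingness, 8% misrecorded parents."""
    cfg = SimConfig(
        seed=12, n_founders_per_breed=30, n_generations=2,
        n_offspring_per_breed_per_gen=40,
    )
    return simulate_herd(cfg)
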