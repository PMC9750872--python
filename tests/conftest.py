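import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import chemscreen as cs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_library() -> cs.SgRNALibrary:
    """4 genes x 5 sgRNAs (one gene with two TSSs) + 11 non-targeting."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    rows = []
    seqs = set()

    def new_seq():
        while True:
            s = "".join(bases[rng.integers(0, 4, 12)])
            if s not in seqs:
                seqs.add(s)
                return s

    for gene, tss in [("ALPHA", "P1"), ("BETA", "P1"), ("GAMMA", "P1"),
                      ("DELTA", "P1"), ("DELTA", "P2")]:
        for k in range(5):
            rows.append({"sgrna_id": f"{gene}_{tss}_sg{k+1}", "sequence": new_seq(),
                         "gene": gene, "tss": tss, "is_nontargeting": False})
    for k in range(11):
        rows.append({"sgrna_id": f"NTC_sg{k+1:02d}", "sequence": new_seq(),
                     "gene": "non-targeting", "tss": "na", "is_nontargeting": True})
    return cs.SgRNALibrary.from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def sim_screen():
    """A moderately deep simulated screen with known truth (shared, read-only)."""
    cfg = cs.SimConfig(n_genes=60, n_nontargeting=80, seed=11,
                       mean_reads_per_sgrna=1000.0)
    lib = cs.simulate_library(cfg)
    counts, truth = cs.simulate_screen(lib, cfg)
    return cfg, lib, counts, truth
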