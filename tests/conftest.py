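import numpy as np
import pandas as pd
import pytest

import cytovar as cv


def make_cytokine_matrix(
    null_vals: dict, stim_vals: dict, stimulation: str = "stim", lloq: float = 0.01
) -> cv.CytokineMatrix:
    """Build a two-condition CytokineMatrix from per-cytokine value lists."""
    cytokines = list(null_vals)
    n = len(next(iter(null_vals.values())))
    donors = pd.Index([f"D{i}" for i in range(n)], name="donor")
    cols = pd.MultiIndex.from_product(
        [["null", stimulation], cytokines], names=["stimulation", "cytokine"]
    )
    values = pd.DataFrame(index=donors, columns=cols, dtype=float)
    for c in cytokines:
        values[("null", c)] = np.asarray(null_vals[c], dtype=float)
        values[(stimulation, c)] = np.asarray(stim_vals[c], dtype=float)
    lloq_s = pd.Series(lloq, index=cols)
    return cv.CytokineMatrix(values, lloq_s, null_condition="null")


@pytest.fixture(scope="session")
def demo_bundle():
    """A mid-sized synthetic cohort with one planted effect of every kind."""
    snps = [cv.SnpSpec(f"rs{i}", "chr1", 9_400_000 + i * 2000, 0.3) for i in range(10)]
    snps[0] = cv.SnpSpec(
        "rs0", "chr1", 9_400_000, 0.3,
        stimulation="E. coli", cytokine="CXCL5", slope=0.8,
    )
    cfg = cv.SimulationConfig(
        n_donors=400,
        stimulations=("null", "E. coli", "SEB", "anti-CD3+CD28"),
        snp_specs=tuple(snps),
        effect_ledger=(
            cv.PlantedEffect("smoking_status", "SEB", "IL-2", np.log(2.0)),
        ),
        mediation_specs=(
            cv.MediationSpec(
                "cmv_seropositive", "CD8_EM", "cell", "SEB", "IFNg",
                alpha=1.2, beta=0.8,
            ),
        ),
        cpg_specs=(cv.CpgSpec("cg_smk_1", "chr1", 10_300_000),),
        n_extra_numeric=2,
        n_extra_categorical=2,
    )
    bundle, truth = cv.simulate_cohort(cfg, seed=20)
    return cfg, bundle, truth
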