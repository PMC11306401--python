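import numpy as np
import pandas as pd
import pytest

from magicrv import SimulationConfig, simulate_linked_dataset


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for unit tests (fast, same structure)."""
    return SimulationConfig(
        n_cases=150,
        n_controls=150,
        n_genes=300,
        baseline_carrier_rate=0.02,
        causal_or=8.0,
        n_cell_types=3,
        cells_per_type=60,
        marker_genes_per_type=10,
        marker_logfc=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_linked(small_config):
    return simulate_linked_dataset(small_config)


@pytest.fixture(scope="session")
def kdelr3_table():
    """Carrier-resolution reconstruction of the three frameshift PTVs with
    case/control allele counts 6/6, 1/3 and 1/2, one variant per sample."""
    n_case, n_ctrl = 449, 9606
    counts = {  # variant_id: (case alleles, control alleles)
        "chr22-38875700-CT-C": (6, 6),
        "chr22-38875736-TAC-T": (1, 3),
        "chr22-38877305-T-TA": (1, 2),
    }
    samples = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_ctrl)]
    dosages = pd.DataFrame(0.0, index=list(counts), columns=samples)
    ci, ui = 0, 0
    for vid, (ac_case, ac_ctrl) in counts.items():
        for _ in range(ac_case):
            dosages.loc[vid, f"case{ci}"] = 1.0
            ci += 1
        for _ in range(ac_ctrl):
            dosages.loc[vid, f"ctrl{ui}"] = 1.0
            ui += 1
    design = pd.DataFrame(
        {"status": [1] * n_case + [0] * n_ctrl}, index=pd.Index(samples, name="sample_id")
    )
    meta = pd.DataFrame(
        {
            "variant_id": list(counts),
            "gene": "KDELR3",
            "variant_class": "PTV",
        }
    ).set_index("variant_id", drop=False)
    return dosages, meta, design
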