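from __future__ import annotations

import numpy as np
import pytest

from tmtquant.differential import differential_analysis
from tmtquant.digest_search import SearchConfig, search_mgf
from tmtquant.quantify import ChannelDesign, QuantConfig, quantify_proteins
from tmtquant.synthetic_data import (SimulationConfig, assign_ground_truth,
                                     generate_proteome, simulate_spectra)


@pytest.fixture(scope="session")
def design() -> ChannelDesign:
    return ChannelDesign()


def run_full_pipeline(sim_config: SimulationConfig,
                      search_config: SearchConfig = SearchConfig(),
                      quant_config: QuantConfig = QuantConfig()):
    """Simulate -> search -> quantify -> DE, entirely in memory.

    Returns (ground truths, DE call table, count summary).
    """
    design = ChannelDesign()
    proteins = generate_proteome(sim_config)
    truths = assign_ground_truth(proteins, sim_config)
    sets = simulate_spectra(proteins, truths, design, sim_config)
    quant_tables = []
    for scans in sets[:2]:
        _accepted, by_protein = search_mgf(proteins, scans, search_config)
        quant_tables.append(
            quantify_proteins(by_protein, scans, design, quant_config))
    calls, summary = differential_analysis(quant_tables[0], quant_tables[1])
    return truths, calls, summary


@pytest.fixture(scope="session")
def zero_noise_run():
    """Deterministic noiseless end-to-end run shared by several tests."""
    cfg = SimulationConfig(n_proteins=100, frac_de_ir=0.2, effect_log2=1.0,
                           noise_sigma=0.0, duplicate_sigma=0.0, seed=42)
    return cfg, *run_full_pipeline(cfg)
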