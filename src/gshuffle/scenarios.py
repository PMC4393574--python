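"""Canonical simulation scenarios used for validation and demos.

These encode the study conditions the simulator is meant to reproduce:
a single multi-mutation founder clone dominating the UV pool (one strong
driver plus linked deleterious passengers), recursive shuffling rounds,
and deep pooled sequencing at the study's mean amplicon coverage.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .calling import CallerConfig, call_frequency_table
from .catalogue import Locus, LocusCatalogue
from .simulate import (
    SimulationConfig,
    founder_pool,
    run_gs_rounds,
    simulate_amplicon_counts,
)
from .trajectory import TrendConfig, build_frequency_matrix, classify_all_trajectories

__all__ = [
    "MEAN_AMPLICON_COVERAGE",
    "UV_FOUNDER_FREQUENCY",
    "hitchhiking_catalogue",
    "hitchhiking_config",
    "hitchhiking_replicate",
    "DRIVER_ID",
    "PASSENGER_IDS",
]

# Study conditions: mean pooled amplicon coverage per nucleotide, and the
# frequency at which the founder clone's mutations sat in the UV pool.
MEAN_AMPLICON_COVERAGE = 1.35e5
UV_FOUNDER_FREQUENCY = 0.60

DRIVER_ID = "driver"
PASSENGER_IDS = ("passenger_1", "passenger_2", "passenger_3", "passenger_4")
_BACKGROUND_IDS = ("bg_1", "bg_2", "bg_3", "bg_4", "bg_5")


def hitchhiking_catalogue() -> LocusCatalogue:
    """One strong driver with four linked deleterious passengers.

    The founder chromosome carries the driver (effect +1.0) flanked by
    passengers (effect -0.2 each) 10 cM apart; five neutral unlinked
    background loci sit on other chromosomes.
    """
    loci = [
        Locus("passenger_1", 1, 20.0, "A", "G", effect_size=-0.2),
        Locus("passenger_2", 1, 30.0, "C", "T", effect_size=-0.2),
        Locus(DRIVER_ID, 1, 40.0, "G", "A", effect_size=1.0),
        Locus("passenger_3", 1, 50.0, "T", "C", effect_size=-0.2),
        Locus("passenger_4", 1, 60.0, "C", "A", effect_size=-0.2),
    ]
    loci += [
        Locus(bid, 2 + i, 0.0, "A", "C", effect_size=0.0)
        for i, bid in enumerate(_BACKGROUND_IDS)
    ]
    return LocusCatalogue(loci)


def hitchhiking_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        population_size=2000,
        uv_mutation_rate=0.5,  # sparse background mutations
        founder_boost=0,  # the founder frequency is set directly
        selection_fraction=0.25,
        fitness_noise_sd=0.3,
        selfing_probability=0.05,
        rounds=5,
        seed=seed,
    )


def hitchhiking_replicate(
    seed: int,
    coverage: float = MEAN_AMPLICON_COVERAGE,
    error_rate: float = 0.0,
    caller: Optional[CallerConfig] = None,
    trend: Optional[TrendConfig] = None,
) -> dict:
    """One seeded founder-clone simulation, observed through pooled
    amplicon sequencing, with trends classified per locus.

    Returns the UV-pool frequencies, the frequency matrix, the per-locus
    trend labels and the truth frequencies of the archived rounds.
    """
    caller = caller or CallerConfig()
    trend = trend or TrendConfig()
    config = hitchhiking_config(seed)
    catalogue = hitchhiking_catalogue()
    rng = config.rng()
    uv = founder_pool(
        catalogue, config, (DRIVER_ID, *PASSENGER_IDS), UV_FOUNDER_FREQUENCY, rng
    )
    samples = run_gs_rounds(config, catalogue, rng=rng, initial_pool=uv)
    counts = pd.concat(
        [
            simulate_amplicon_counts(s, catalogue, coverage, error_rate, rng)
            for s in samples
        ],
        ignore_index=True,
    )
    freq = call_frequency_table(counts, caller)
    matrix = build_frequency_matrix(freq, round_order=[s.round_label for s in samples])
    trends = classify_all_trajectories(matrix, trend)
    uv_freqs = freq[freq["sample"] == "UV"].set_index("locus_id")["frequency"]
    truth = {s.round_label: s.allele_frequencies() for s in samples}
    return {
        "catalogue": catalogue,
        "uv_frequencies": uv_freqs.to_dict(),
        "matrix": matrix,
        "trends": dict(zip(trends["locus_id"], trends["trend"])),
        "truth": truth,
    }
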