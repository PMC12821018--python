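"""End-to-end compositions: generator -> curve fits -> maps -> statistics.

These helpers wire the stages together for whole simulated experiments,
so that recovery of generator ground truth (moduli, compartment ratios,
temperature slopes) can be measured with one call. The CLI uses the same
code paths on curves read from disk.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mapping import assemble_map, summarize_map
from .processing import process_batch
from .stats import regression_report
from .synthetic import (
    NoiseModel,
    Protocol,
    SimulatedMap,
    TissuePhantom,
    make_phantom,
    simulate_experiment,
)

__all__ = [
    "fit_simulated_map",
    "summarize_simulated_maps",
    "temperature_study",
]


def fit_simulated_map(sim: SimulatedMap, model: str = "hertz", **kwargs):
    """Run the full per-curve pipeline on one simulated map.

    Returns ``(results, emap, summary)``: the per-curve result table, the
    assembled :class:`~elastimap.mapping.ElasticityMap` with the phantom's
    true compartment labels, and its :class:`CompartmentSummary`.
    """
    results = process_batch(sim.curves, model=model, **kwargs)
    emap = assemble_map(results, sim.manifest[["x_um", "y_um", "label"]].copy(),
                        on_missing="drop",
                        setpoint_force=sim.condition["setpoint_force"],
                        setpoint_speed=sim.condition["speed"])
    summary = summarize_map(emap)
    return results, emap, summary


def summarize_simulated_maps(
    maps: Sequence[SimulatedMap],
    model: str = "hertz",
    **kwargs,
) -> pd.DataFrame:
    """Per-map summaries for a list of simulated conditions.

    The output carries one row per map: the condition columns plus the
    compartment-summary schema (medians, ratio, counts, paired times and
    temperatures).
    """
    rows = []
    for sim in maps:
        _, _, summary = fit_simulated_map(sim, model=model, **kwargs)
        row = {
            "setpoint_force_nN": sim.condition["setpoint_force"] * 1e9,
            "setpoint_speed_um_per_s": sim.condition["speed"] * 1e6,
            "postmortem_h": sim.condition["t_pm"],
            "temperature_C": sim.condition["temperature"],
        }
        row.update(summary.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def temperature_study(
    seed: int = 0,
    n_animals: int = 6,
    temperatures: Sequence[float] = (20.0, 24.5, 29.0, 33.5, 38.0),
    preset: str = "transverse",
    grid_resolution: float = 450e-6,
    noise: Optional[NoiseModel] = None,
    animal_sd: float = 0.15,
    t_pm: float = 2.5,
    model: str = "hertz",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate and analyse a multi-animal temperature experiment.

    Each animal is a phantom whose base moduli carry a lognormal
    animal-to-animal factor (SD ``animal_sd`` on the log scale); the same
    map grid is remeasured at every temperature level, fitted, and
    summarised per map. The returned report regresses the per-map medians
    (and their ratio) on temperature with the linear-vs-constant F-test.

    Returns ``(summaries, report, truth)`` where ``truth`` holds the
    generator's relative slopes (%/degC) per compartment.
    """
    base_phantom = make_phantom(preset)
    if noise is None:
        noise = NoiseModel(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xA11A,)))
    all_rows = []
    for animal in range(n_animals):
        # gray and white vary independently across animals, so the ratio
        # itself scatters between animals as it does in real sections
        factor_g = float(np.exp(rng.normal(0.0, animal_sd)))
        factor_w = float(np.exp(rng.normal(0.0, animal_sd)))
        phantom = base_phantom.scaled(factor_g, factor_w)
        protocol = Protocol(
            grid_resolution=grid_resolution,
            temperatures=tuple(temperatures),
            timepoints=(t_pm,),
            seed=int(np.random.SeedSequence(seed, spawn_key=(animal + 1,))
                     .generate_state(1)[0] % (2 ** 31)),
            noise=noise,
            model=model,
        )
        maps = simulate_experiment(phantom, protocol)
        summaries = summarize_simulated_maps(maps, model=model)
        summaries.insert(0, "animal", animal)
        all_rows.append(summaries)
    summaries = pd.concat(all_rows, ignore_index=True)
    report = regression_report(summaries, x_mode="temperature")
    truth = {"rho_gray": base_phantom.gray.rho, "rho_white": base_phantom.white.rho}
    return summaries, report, truth
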