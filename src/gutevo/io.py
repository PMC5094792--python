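"""CSV/JSON/YAML readers and writers for the toolkit's tabular formats.

Formats:

* competition trajectories — CSV with columns ``day, replicate,
  count_focal, count_reference`` (optional ``gat_phenotype`` strata
  columns pass through untouched),
* fluctuation tables — CSV with columns ``culture, mutant_count, nt``,
* simulation configuration — YAML/JSON mirroring
  :class:`gutevo.synthetic_data.SimulationConfig`.

Mutation tables and coverage profiles read/write themselves (see
:mod:`gutevo.genome_analysis`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .fluctuation_analysis import FluctuationExperiment
from .selection_inference import CompetitionTrajectory, DEFAULT_GENERATIONS_PER_DAY
from .synthetic_data import LocusSpec, SamplingSpec, SimulationConfig

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_fluctuation",
    "read_fluctuation",
    "config_to_yaml",
    "config_from_yaml",
]


def write_trajectories(trajectories: Iterable[CompetitionTrajectory], path) -> None:
    frames = []
    for i, traj in enumerate(trajectories):
        frames.append(
            pd.DataFrame(
                {
                    "day": traj.day,
                    "replicate": traj.replicate_id or f"rep{i + 1}",
                    "count_focal": traj.focal_count,
                    "count_reference": traj.reference_count,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(
    path, generations_per_day: int = DEFAULT_GENERATIONS_PER_DAY
) -> list[CompetitionTrajectory]:
    df = pd.read_csv(path)
    out = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("day")
        counts = grp[["count_focal", "count_reference"]].to_numpy(dtype=float)
        out.append(
            CompetitionTrajectory(
                day=grp["day"].to_numpy(),
                focal_count=counts[:, 0],
                reference_count=counts[:, 1],
                generations_per_day=generations_per_day,
                replicate_id=str(rep),
                is_frequency=bool((counts.sum(axis=1) <= 1.0 + 1e-9).all()),
            )
        )
    return out


def write_fluctuation(experiment: FluctuationExperiment, path) -> None:
    pd.DataFrame(
        {
            "culture": range(1, experiment.n_cultures + 1),
            "mutant_count": experiment.mutant_counts,
            "nt": experiment.nt,
        }
    ).to_csv(path, index=False)


def read_fluctuation(path, nt: float | None = None) -> FluctuationExperiment:
    df = pd.read_csv(path)
    if nt is None:
        if "nt" not in df.columns:
            raise ValueError("nt column absent: pass nt explicitly")
        nt = float(df["nt"].iloc[0])
    return FluctuationExperiment(
        mutant_counts=df["mutant_count"].to_numpy(dtype=int), nt=nt
    )


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    for locus in d["loci"]:
        locus["epistasis_overrides"] = {
            "+".join(sorted(k)): v for k, v in locus["epistasis_overrides"].items()
        }
        if isinstance(locus["fitness_effect"], tuple):
            locus["fitness_effect"] = list(locus["fitness_effect"])
    return d


def config_to_yaml(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_dict(config), sort_keys=False))


def config_from_yaml(path) -> SimulationConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    loci = []
    for locus in data.get("loci", []):
        eff = locus.get("fitness_effect", 0.0)
        if isinstance(eff, list):
            eff = tuple(eff)
        loci.append(
            LocusSpec(
                name=locus["name"],
                mutation_rate=locus.get("mutation_rate", 0.0),
                fitness_effect=eff,
                epistasis_overrides={
                    frozenset(k.split("+")): v
                    for k, v in locus.get("epistasis_overrides", {}).items()
                },
                initial_frequency=locus.get("initial_frequency", 0.0),
            )
        )
    sampling = SamplingSpec(**data.get("sampling", {}))
    return SimulationConfig(
        population_size=float(data.get("population_size", 1e7)),
        generations_per_day=int(data.get("generations_per_day", 18)),
        days=int(data.get("days", 24)),
        loci=loci,
        marker_split=float(data.get("marker_split", 0.5)),
        sampling=sampling,
        rng_seed=int(data.get("rng_seed", 0)),
        deterministic=bool(data.get("deterministic", False)),
    )
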