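"""Reading and writing the package's file formats.

Constraint-based networks come in either as SBML (through cobrapy, when
installed) or as a plain two-file TSV format: a stoichiometry triple table
(metabolite, reaction, coefficient) plus a bounds table (reaction, lower,
upper).  Kinetics and objective hierarchies ride in YAML run configs.
Trajectories, experimental designs, datasets and particle ensembles are
exchanged as CSV; surrogates are serialized to self-describing JSON
archives with a schema version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dfba import MetabolicNetwork, Trajectory
from .pce import ExperimentalDesign, SparsePCE
from .space import ParameterSpace
from .surrogate import NsPCESurrogate, SingularitySurrogate
from .uq import Dataset, ParticleEnsemble

__all__ = [
    "read_network_tsv",
    "write_network_tsv",
    "read_network_sbml",
    "trajectory_to_frame",
    "write_trajectory_csv",
    "write_events_csv",
    "ed_to_csv",
    "ed_from_csv",
    "dataset_to_csv",
    "dataset_from_csv",
    "ensemble_to_csv",
    "save_surrogate",
    "load_surrogate",
    "load_run_config",
]


def read_network_tsv(stoich_path, bounds_path, exchange_map: dict | None = None) -> MetabolicNetwork:
    """Assemble a network from (metabolite, reaction, coefficient) triples
    and a (reaction, lower, upper) bounds table."""
    tri = pd.read_csv(stoich_path, sep="\t")
    bnd = pd.read_csv(bounds_path, sep="\t")
    for col in ("metabolite", "reaction", "coefficient"):
        if col not in tri.columns:
            raise ValueError(f"stoichiometry table is missing column {col!r}")
    for col in ("reaction", "lower", "upper"):
        if col not in bnd.columns:
            raise ValueError(f"bounds table is missing column {col!r}")
    reactions = list(dict.fromkeys(bnd["reaction"]))
    metabolites = list(dict.fromkeys(tri["metabolite"]))
    S = np.zeros((len(metabolites), len(reactions)))
    rindex = {r: j for j, r in enumerate(reactions)}
    mindex = {m: i for i, m in enumerate(metabolites)}
    for _, row in tri.iterrows():
        if row["reaction"] not in rindex:
            raise ValueError(f"stoichiometry references unknown reaction {row['reaction']!r}")
        S[mindex[row["metabolite"]], rindex[row["reaction"]]] = float(row["coefficient"])
    lb = bnd["lower"].to_numpy(dtype=float)
    ub = bnd["upper"].to_numpy(dtype=float)
    return MetabolicNetwork(S, lb, ub, tuple(reactions), tuple(metabolites),
                            dict(exchange_map or {}))


def write_network_tsv(network: MetabolicNetwork, stoich_path, bounds_path) -> None:
    rows = []
    S = network.stoichiometry
    for i, met in enumerate(network.metabolite_ids):
        for j, rxn in enumerate(network.reaction_ids):
            if S[i, j] != 0.0:
                rows.append((met, rxn, S[i, j]))
    pd.DataFrame(rows, columns=["metabolite", "reaction", "coefficient"]).to_csv(
        stoich_path, sep="\t", index=False)
    pd.DataFrame({
        "reaction": network.reaction_ids,
        "lower": network.flux_lower,
        "upper": network.flux_upper,
    }).to_csv(bounds_path, sep="\t", index=False)


def read_network_sbml(path, exchange_map: dict | None = None) -> MetabolicNetwork:
    """Load a constraint-based model from SBML (fbc) via cobrapy."""
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading SBML networks requires the optional cobrapy dependency") from exc
    cm = cobra.io.read_sbml_model(str(path))
    reactions = tuple(r.id for r in cm.reactions)
    metabolites = tuple(m.id for m in cm.metabolites)
    S = cobra.util.array.create_stoichiometric_matrix(cm)
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    return MetabolicNetwork(S, lb, ub, reactions, metabolites, dict(exchange_map or {}))


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    df = pd.DataFrame(traj.states, columns=list(traj.state_ids))
    df.insert(0, "time", traj.times)
    return df


def write_trajectory_csv(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def write_events_csv(traj: Trajectory, path) -> None:
    pd.DataFrame(
        [(e.time, e.label, repr(e.signature_before), repr(e.signature_after)) for e in traj.events],
        columns=["time", "label", "active_set_before", "active_set_after"],
    ).to_csv(path, index=False)


def ed_to_csv(ed: ExperimentalDesign, path, names=None) -> None:
    cols = list(names) if names else [f"x{i + 1}" for i in range(ed.X.shape[1])]
    df = pd.DataFrame(ed.X, columns=cols)
    if ed.Y is not None:
        df["response"] = ed.Y
    if ed.T_singularity is not None:
        df["t_singularity"] = ed.T_singularity
    df.to_csv(path, index=False)


def ed_from_csv(path) -> ExperimentalDesign:
    df = pd.read_csv(path)
    y = df.pop("response").to_numpy() if "response" in df.columns else None
    ts = df.pop("t_singularity").to_numpy() if "t_singularity" in df.columns else None
    return ExperimentalDesign(df.to_numpy(dtype=float), y, ts)


def dataset_to_csv(ds: Dataset, path) -> None:
    ds.to_frame().to_csv(path, index=False)


def dataset_from_csv(path) -> Dataset:
    return Dataset.from_frame(pd.read_csv(path))


def ensemble_to_csv(ens: ParticleEnsemble, path, names=None) -> None:
    cols = list(names) if names else [f"x{i + 1}" for i in range(ens.particles.shape[1])]
    df = pd.DataFrame(ens.particles, columns=cols)
    df["weight"] = ens.weights
    df.to_csv(path, index=False)


def save_surrogate(obj, path) -> None:
    """Serialize a SparsePCE / SingularitySurrogate / NsPCESurrogate."""
    Path(path).write_text(json.dumps(obj.to_dict(), indent=1, sort_keys=True))


def load_surrogate(path):
    d = json.loads(Path(path).read_text())
    schema = d.get("schema", "")
    if schema.startswith("nspce.SparsePCE"):
        return SparsePCE.from_dict(d)
    if schema.startswith("nspce.SingularitySurrogate"):
        return SingularitySurrogate.from_dict(d)
    if schema.startswith("nspce.NsPCESurrogate"):
        return NsPCESurrogate.from_dict(d)
    raise ValueError(f"unknown surrogate schema {schema!r}")


def load_run_config(path) -> dict:
    """Read and validate a YAML run configuration."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    cfg.setdefault("eps_target", 1e-3)
    cfg.setdefault("n_init", 20)
    cfg.setdefault("n_add", 10)
    cfg.setdefault("n_max", 200)
    cfg.setdefault("p_max", 10)
    cfg.setdefault("q", 0.75)
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "nspce_run")
    if cfg["eps_target"] <= 0:
        raise ValueError("eps_target must be positive")
    if cfg["n_init"] > cfg["n_max"]:
        raise ValueError("n_init must be <= n_max")
    return cfg


def space_from_config(d) -> ParameterSpace:
    from .space import Marginal

    margs = []
    names = []
    for item in d:
        names.append(item["name"])
        fam = item.get("family", "uniform")
        if fam == "uniform":
            margs.append(Marginal("uniform", float(item["lower"]), float(item["upper"])))
        else:
            margs.append(Marginal("gaussian", float(item["mean"]), float(item["sd"])))
    return ParameterSpace(tuple(margs), tuple(names))
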