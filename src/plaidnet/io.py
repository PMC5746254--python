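"""Serialisation helpers: Matrix Market weights, YAML configs, HDF5 runs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy import io as spio
from scipy import sparse

from .builder import ConnectivitySpec, SynapseMatrix
from .ratenet import NetworkModel, NeuronParams, RateTrajectory

__all__ = [
    "save_network_model",
    "load_network_model",
    "save_synapse_counts",
    "load_synapse_counts",
    "save_trajectory_hdf5",
    "load_trajectory_hdf5",
    "trajectory_to_csv",
    "spec_to_yaml",
    "spec_from_yaml",
    "phase_diagram_to_csv",
    "plot_phase_diagram",
    "response_table_to_hdf5",
    "response_table_from_hdf5",
    "bootstrap_control_to_csv",
]


def save_network_model(model: NetworkModel, path_prefix) -> None:
    """Write weights as MTX plus a YAML sidecar of per-neuron parameters."""
    prefix = Path(path_prefix)
    w = model.weights
    spio.mmwrite(str(prefix.with_suffix(".mtx")),
                 sparse.coo_matrix(w) if not sparse.issparse(w) else w)
    params = {k: np.asarray(v).tolist()
              for k, v in asdict(model.params).items()}
    with open(prefix.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump({"n_neurons": model.n_neurons, "params": params}, fh)


def load_network_model(path_prefix) -> NetworkModel:
    prefix = Path(path_prefix)
    weights = spio.mmread(str(prefix.with_suffix(".mtx"))).tocsr()
    with open(prefix.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    params = NeuronParams(**{k: np.asarray(v)
                             for k, v in meta["params"].items()})
    return NetworkModel(weights, params)


def save_synapse_counts(syn: SynapseMatrix, path) -> None:
    spio.mmwrite(str(path), syn.counts)


def load_synapse_counts(path) -> sparse.csc_matrix:
    return spio.mmread(str(path)).tocsc()


def save_trajectory_hdf5(traj: RateTrajectory, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("activations", data=traj.activations)
        fh.create_dataset("rates", data=traj.rates)
        fh.attrs["diverged"] = traj.diverged


def load_trajectory_hdf5(path) -> RateTrajectory:
    with h5py.File(path, "r") as fh:
        return RateTrajectory(times=fh["times"][:],
                              activations=fh["activations"][:],
                              rates=fh["rates"][:],
                              diverged=bool(fh.attrs["diverged"]))


def trajectory_to_csv(traj: RateTrajectory, path) -> None:
    n = traj.activations.shape[1]
    header = ",".join(["time_ms"]
                      + [f"x_{i}" for i in range(n)]
                      + [f"rate_{i}" for i in range(n)])
    data = np.column_stack([traj.times, traj.activations, traj.rates])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def phase_diagram_to_csv(diagram, path) -> None:
    """One row per grid cell: axis values, regime label, competition."""
    import pandas as pd

    n1, n2 = diagram.regimes.shape
    rows = []
    for i in range(n1):
        for j in range(n2):
            rows.append({
                diagram.axis_names[0]: diagram.axis_values[0][i],
                diagram.axis_names[1]: diagram.axis_values[1][j],
                "regime": diagram.regimes[i, j],
                "competition_pA": diagram.competition[i, j],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def plot_phase_diagram(diagram, path) -> None:
    """Regime map as a coloured grid (competition overlaid where stable)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = ["AS", "ISN", "Exp", "IO"]
    codes = np.vectorize(order.index)(diagram.regimes)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(codes.T, origin="lower", aspect="auto", cmap="viridis",
                   vmin=0, vmax=3,
                   extent=[diagram.axis_values[0][0],
                           diagram.axis_values[0][-1],
                           diagram.axis_values[1][0],
                           diagram.axis_values[1][-1]])
    ax.set_xlabel(diagram.axis_names[0])
    ax.set_ylabel(diagram.axis_names[1])
    cbar = fig.colorbar(im, ticks=range(4))
    cbar.ax.set_yticklabels(order)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def response_table_to_hdf5(table, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("responses", data=table.responses)
        fh.create_dataset("stimulus_kinds",
                          data=np.asarray(table.stimulus_kinds, dtype="S"))


def response_table_from_hdf5(path):
    from .metrics import ResponseTable

    with h5py.File(path, "r") as fh:
        return ResponseTable(fh["responses"][:],
                             fh["stimulus_kinds"][:].astype(str))


def bootstrap_control_to_csv(result, csv_path, json_path=None) -> None:
    """Per-sample R^2 values as CSV plus an optional JSON summary."""
    import pandas as pd

    pd.DataFrame({"sample_id": np.arange(len(result.r2_samples)),
                  "r2": result.r2_samples}).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({"median": result.median, "ci_low": result.ci_low,
                       "ci_high": result.ci_high, "seed": result.seed},
                      fh, indent=2)


def spec_to_yaml(spec: ConnectivitySpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh)


def spec_from_yaml(path) -> ConnectivitySpec:
    with open(path) as fh:
        return ConnectivitySpec(**yaml.safe_load(fh))
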