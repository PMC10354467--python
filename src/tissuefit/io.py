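"""Delimited-text readers and writers for snapshots, observations, chains.

All artifacts are plain text: density snapshots carry their grid metadata
in ``#`` header lines (one row per grid row, species blocks stacked);
observation sets are long-format tables (x, y, t, rho_D); chains are CSV
with one row per iteration per chain.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid, MultiSpeciesState
from .inference import PARAM_NAMES, ChainSet
from .observations import ObservationSet

__all__ = [
    "write_state",
    "read_state",
    "write_observations",
    "read_observations",
    "write_chains",
    "read_chains",
]


def write_state(state: MultiSpeciesState, path) -> None:
    path = Path(path)
    g = state.grid
    header = "\n".join(
        [
            "tissuefit density snapshot (cells mm^-2)",
            f"mode: {g.mode}",
            f"h: {g.h!r}",
            f"shape: {' '.join(map(str, g.shape))}",
            f"origin: {' '.join(repr(v) for v in g.origin)}",
            f"time: {state.time!r}",
            f"n_species: {state.n_species}",
        ]
    )
    flat = state.densities.reshape(-1, g.shape[-1])
    np.savetxt(path, flat, header=header)


def read_state(path) -> MultiSpeciesState:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            txt = line[1:].strip()
            if ":" in txt:
                key, _, val = txt.partition(":")
                meta[key.strip()] = val.strip()
    shape = tuple(int(v) for v in meta["shape"].split())
    grid = Grid(
        meta["mode"],
        float(meta["h"]),
        shape,
        tuple(float(v) for v in meta["origin"].split()),
    )
    ns = int(meta["n_species"])
    flat = np.loadtxt(path, ndmin=2)
    return MultiSpeciesState(grid, flat.reshape((ns, *shape)), float(meta["time"]))


def write_observations(obs: ObservationSet, path) -> None:
    path = Path(path)
    rows = []
    for j, t in enumerate(obs.times):
        for i, (x, y) in enumerate(obs.positions):
            rows.append((x, y, t, obs.values[j, i]))
    df = pd.DataFrame(rows, columns=["x", "y", "t", "rho_D"])
    with open(path, "w") as fh:
        fh.write("# tissuefit observation set\n")
        fh.write(f"# voxel_um: {obs.voxel!r}\n")
        fh.write(f"# sigma_true: {obs.sigma_true!r}\n")
        fh.write(f"# seed: {obs.seed!r}\n")
        df.to_csv(fh, index=False, sep="\t")


def read_observations(path) -> ObservationSet:
    import io as _io

    meta = {}
    text = Path(path).read_text().splitlines(keepends=True)
    body = 0
    for line in text:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition(":")
        meta[key.strip()] = val.strip()
        body += 1
    df = pd.read_csv(_io.StringIO("".join(text[body:])), sep="\t")
    times = np.unique(df["t"].to_numpy())
    first = df[df["t"] == times[0]]
    positions = first[["x", "y"]].to_numpy()
    values = np.stack(
        [df[df["t"] == t]["rho_D"].to_numpy() for t in times]
    )

    def _opt(key):
        v = meta.get(key, "None")
        return None if v == "None" else float(v)

    seed = _opt("seed")
    return ObservationSet(
        positions=positions,
        times=times,
        values=values,
        voxel=float(meta["voxel_um"]),
        sigma_true=_opt("sigma_true"),
        seed=None if seed is None else int(seed),
    )


def write_chains(chains: ChainSet, path) -> None:
    df = chains.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# retain: {chains.retain}\n")
        df.to_csv(fh, index=False)


def read_chains(path) -> ChainSet:
    with open(path) as fh:
        first = fh.readline()
        retain = int(first.partition(":")[2]) if first.startswith("#") else 5000
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh)
    n_chains = df["chain"].nunique()
    n_iter = df["iteration"].nunique()
    samples = np.empty((n_chains, n_iter, len(PARAM_NAMES)))
    log_post = np.empty((n_chains, n_iter))
    accepted = np.empty((n_chains, n_iter), dtype=bool)
    for c, sub in df.groupby("chain"):
        sub = sub.sort_values("iteration")
        samples[c] = sub[list(PARAM_NAMES)].to_numpy()
        log_post[c] = sub["log_post"].to_numpy()
        accepted[c] = sub["accepted"].to_numpy().astype(bool)
    return ChainSet(samples, log_post, accepted, retain=retain)
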