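"""File formats: snapshots, edge lists, trajectory containers, tables.

All formats are plain text (JSON or comma-separated with commented
headers) and round-trip floating-point payloads exactly: floats are
serialized with Python's shortest round-trip ``repr``.  A trajectory is a
directory container::

    traj/
      meta.json          # params, protocol config, seed, schema version
      frames/00000.json  # positions, gamma, energy, sigma, G, residual
      events.csv         # one row per T1 event
      avalanches.csv     # optional avalanche summary

so every frame is readable independently.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np

from .geometry import EdgeEnsemble, TissueState
from .mechanics import EnergyParams
from .plasticity import Avalanche, T1Event
from .shear import FireConfig, Frame, ProtocolConfig, Trajectory

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Malformed input file; the message names the file, line and field."""


# --------------------------------------------------------------------------
# snapshots
# --------------------------------------------------------------------------

def write_snapshot(state: TissueState, path: str) -> None:
    doc = {
        "format": "voroshear-snapshot",
        "version": SCHEMA_VERSION,
        "n": state.n,
        "box": [state.box[0], state.box[1]],
        "gamma": state.gamma,
        "seed": state.seed,
        "positions": [[float(x), float(y)] for x, y in state.positions],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_snapshot(path: str) -> TissueState:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as err:
            raise FormatError(f"{path}: invalid JSON: {err}") from err
    for key in ("n", "box", "gamma", "positions"):
        if key not in doc:
            raise FormatError(f"{path}: missing snapshot field {key!r}")
    pos = np.asarray(doc["positions"], dtype=float)
    if pos.shape != (int(doc["n"]), 2):
        raise FormatError(
            f"{path}: field 'positions' has shape {pos.shape}, expected "
            f"({doc['n']}, 2)")
    return TissueState(pos, tuple(doc["box"]), float(doc["gamma"]),
                       seed=int(doc.get("seed") or 0))


# --------------------------------------------------------------------------
# edge lists
# --------------------------------------------------------------------------

def write_edge_list(ensemble: EdgeEnsemble, path: str) -> None:
    """Tabular edge list: one row per edge, ``length,orientation_deg``.

    Frame metadata (gamma, sigma) goes into comment lines.  Coordinates
    convention for endpoint-style files is 0-based, y-up.
    """
    with open(path, "w") as fh:
        fh.write("# voroshear-edges v%d\n" % SCHEMA_VERSION)
        if ensemble.gamma is not None:
            fh.write(f"# gamma = {float(ensemble.gamma)!r}\n")
        if ensemble.sigma is not None:
            fh.write(f"# sigma = {float(ensemble.sigma)!r}\n")
        fh.write("# columns: length,orientation_deg\n")
        for l, w in zip(ensemble.l, ensemble.omega):
            fh.write(f"{float(l)!r},{float(w)!r}\n")


def read_edge_list(path: str) -> EdgeEnsemble:
    """Read an edge list: 2 columns (length, orientation_degrees) or
    4 columns (x1, y1, x2, y2) per row; header comments may carry gamma
    and sigma metadata.  Lengths are re-normalized to mean 1."""
    lengths, omegas = [], []
    gamma = sigma = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                for key in ("gamma", "sigma"):
                    if body.startswith(key):
                        try:
                            val = float(body.split("=", 1)[1])
                        except (IndexError, ValueError):
                            raise FormatError(
                                f"{path}:{ln}: malformed {key} header")
                        if key == "gamma":
                            gamma = val
                        else:
                            sigma = val
                continue
            parts = line.split(",")
            if len(parts) not in (2, 4):
                raise FormatError(
                    f"{path}:{ln}: expected 2 or 4 comma-separated fields, "
                    f"got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as err:
                raise FormatError(f"{path}:{ln}: non-numeric field: {err}") \
                    from err
            if len(vals) == 2:
                L, w = vals
                if L <= 0:
                    raise FormatError(
                        f"{path}:{ln}: field 'length' must be positive, "
                        f"got {L!r}")
                if not 0.0 <= w < 180.0:
                    raise FormatError(
                        f"{path}:{ln}: field 'orientation_deg' must lie in "
                        f"[0, 180), got {w!r}")
            else:
                x1, y1, x2, y2 = vals
                dx, dy = x2 - x1, y2 - y1
                L = float(np.hypot(dx, dy))
                if L <= 0:
                    raise FormatError(
                        f"{path}:{ln}: zero-length edge from endpoints")
                w = float(np.degrees(np.arctan2(dy, dx)) % 180.0)
            lengths.append(L)
            omegas.append(w)
    if not lengths:
        raise FormatError(f"{path}: edge list contains no edges")
    l = np.asarray(lengths)
    return EdgeEnsemble(l=l / l.mean(), omega=np.asarray(omegas),
                        gamma=gamma, sigma=sigma)


# --------------------------------------------------------------------------
# result tables
# --------------------------------------------------------------------------

def write_table(path: str, columns: dict) -> None:
    """Comma-separated table with a commented header row."""
    names = list(columns)
    arrays = [np.asarray(columns[k]) for k in names]
    n = len(arrays[0])
    with open(path, "w") as fh:
        fh.write("# " + ",".join(names) + "\n")
        for i in range(n):
            fh.write(",".join(repr(float(a[i])) for a in arrays) + "\n")


def read_table(path: str) -> dict:
    """Inverse of :func:`write_table`."""
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"{path}: missing commented header row")
    names = [c.strip() for c in lines[0].lstrip("#").split(",")]
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != len(names):
            raise FormatError(
                f"{path}:{ln}: expected {len(names)} fields, "
                f"got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as err:
            raise FormatError(f"{path}:{ln}: non-numeric field: {err}") \
                from err
    data = np.array(rows) if rows else np.empty((0, len(names)))
    return {name: data[:, i] for i, name in enumerate(names)}


# --------------------------------------------------------------------------
# trajectory container
# --------------------------------------------------------------------------

EVENT_COLUMNS = "strain_index,fire_time,x,y,i,j,k,l"
AVALANCHE_COLUMNS = "strain_index,size,stress_drop,type,precursor_modulus"


def save_trajectory(traj: Trajectory, path: str,
                    avalanches: list | None = None) -> None:
    os.makedirs(os.path.join(path, "frames"), exist_ok=True)
    meta = {
        "format": "voroshear-trajectory",
        "version": SCHEMA_VERSION,
        "params": asdict(traj.params),
        "config": asdict(traj.config),
        "n_frames": len(traj.frames),
        "n_events": len(traj.t1_events),
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    for fr in traj.frames:
        doc = {
            "index": fr.index,
            "gamma": fr.gamma,
            "energy": fr.energy,
            "sigma": fr.sigma,
            "residual": fr.residual,
            "fire_iterations": fr.fire_iterations,
            "shear_modulus": fr.shear_modulus,
            "box": [fr.state.box[0], fr.state.box[1]],
            "seed": fr.state.seed,
            "positions": [[float(x), float(y)] for x, y in
                          fr.state.positions],
        }
        with open(os.path.join(path, "frames", f"{fr.index:05d}.json"),
                  "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")
    with open(os.path.join(path, "events.csv"), "w") as fh:
        fh.write("# " + EVENT_COLUMNS + "\n")
        for e in traj.t1_events:
            i, j, k, l = e.quad
            fh.write(f"{e.strain_index},{e.fire_time},"
                     f"{float(e.position[0])!r},{float(e.position[1])!r},"
                     f"{i},{j},{k},{l}\n")
    if avalanches is not None:
        write_avalanche_table(avalanches,
                              os.path.join(path, "avalanches.csv"))


def write_avalanche_table(avalanches, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# " + AVALANCHE_COLUMNS + "\n")
        for a in avalanches:
            fh.write(f"{a.strain_index},{a.size},{a.stress_drop!r},"
                     f"{a.type},{a.precursor_modulus!r}\n")


def load_trajectory(path: str) -> Trajectory:
    """Rebuild a :class:`Trajectory` from a container directory.

    Frame adjacency fingerprints are not stored (events are); loaded
    frames carry empty adjacency sets.
    """
    meta_path = os.path.join(path, "meta.json")
    if not os.path.exists(meta_path):
        raise FormatError(f"{path}: not a trajectory container "
                          "(meta.json missing)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    params = EnergyParams(**meta["params"])
    cfg_doc = dict(meta["config"])
    fire = FireConfig(**cfg_doc.pop("fire"))
    config = ProtocolConfig(fire=fire, **cfg_doc)
    frames = []
    for k in range(int(meta["n_frames"])):
        fp = os.path.join(path, "frames", f"{k:05d}.json")
        if not os.path.exists(fp):
            raise FormatError(f"{path}: frame {k} missing ({fp})")
        with open(fp) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as err:
                raise FormatError(
                    f"{fp}: truncated or invalid frame: {err}") from err
        state = TissueState(np.asarray(doc["positions"], float),
                            tuple(doc["box"]), float(doc["gamma"]),
                            seed=int(doc.get("seed") or 0))
        frames.append(Frame(
            index=int(doc["index"]), gamma=float(doc["gamma"]),
            state=state, energy=float(doc["energy"]),
            sigma=float(doc["sigma"]), residual=float(doc["residual"]),
            fire_iterations=int(doc["fire_iterations"]),
            adjacency=frozenset(),
            shear_modulus=float(doc["shear_modulus"])))
    events = []
    ev_path = os.path.join(path, "events.csv")
    if os.path.exists(ev_path):
        tab = read_table(ev_path)
        for r in range(len(tab["strain_index"])):
            events.append(T1Event(
                strain_index=int(tab["strain_index"][r]),
                fire_time=int(tab["fire_time"][r]),
                position=np.array([tab["x"][r], tab["y"][r]]),
                quad=(int(tab["i"][r]), int(tab["j"][r]),
                      int(tab["k"][r]), int(tab["l"][r]))))
    return Trajectory(params=params, config=config, frames=frames,
                      t1_events=events)


def load_avalanche_table(path: str) -> list:
    """Read an avalanche summary written by :func:`write_avalanche_table`.

    Events are not reconstructed; each avalanche carries an empty event
    list but the stored size in ``stored_size``.
    """
    out = []
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    for ln, line in enumerate(lines, start=1):
        if line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 5:
            raise FormatError(f"{path}:{ln}: expected 5 fields, "
                              f"got {len(parts)}")
        a = Avalanche(events=[], stress_drop=float(parts[2]),
                      type=parts[3], strain_index=int(parts[0]),
                      precursor_modulus=float(parts[4]))
        a.stored_size = int(parts[1])
        out.append(a)
    return out
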