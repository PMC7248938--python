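"""Readers and writers for the on-disk formats.

One self-describing HDF5 container per run holds the arrays (raw data,
features, MPC matrix, cortical map); events are a two-column TSV, meshes are
OFF-format text with a per-vertex label TSV, and summaries are TSV/JSON.
All round-trips are lossless (arrays bit-exact, metadata exact).
"""

from __future__ import annotations

import numpy as np
import h5py

from .correlation import MPCMap
from .features import TFFeatures
from .projection import CorticalMap
from .synthetic import CorticalMesh, RawSession

__all__ = [
    "write_session", "read_session",
    "write_events", "read_events",
    "write_mesh", "read_mesh",
    "write_labels", "read_labels",
    "write_features", "read_features",
    "write_mpc", "read_mpc",
    "write_cortical_map_values", "read_cortical_map_values",
    "mpc_long_table", "write_mpc_tsv",
    "write_region_tsv", "write_vertex_tsv",
]


# -- HDF5 container -----------------------------------------------------------

def write_session(path, session: RawSession, mode: str = "w") -> None:
    with h5py.File(path, mode) as f:
        f.create_dataset("data", data=session.data)
        f.create_dataset("fs", data=session.fs)
        f.create_dataset("channel_locus", data=session.channel_locus)
        f.create_dataset("locus_pos", data=session.locus_positions)


def read_session(path) -> RawSession:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f["fs"][()])
        channel_locus = f["channel_locus"][()]
        locus_pos = f["locus_pos"][()]
    if data.shape[0] != channel_locus.shape[0]:
        raise ValueError(
            f"channel_locus has {channel_locus.shape[0]} entries but data "
            f"has {data.shape[0]} channels"
        )
    return RawSession(data=data, fs=fs, channel_locus=channel_locus,
                      locus_positions=locus_pos)


def write_features(path, features: TFFeatures) -> None:
    with h5py.File(path, "a") as f:
        if "features" in f:
            del f["features"]
        g = f.create_group("features")
        g.create_dataset("values", data=features.values)
        g.create_dataset("frame_times", data=features.frame_times)
        g.attrs["window"] = features.window
        g.attrs["step"] = features.step
        if features.channel_locus is not None:
            g.create_dataset("channel_locus", data=features.channel_locus)


def read_features(path) -> TFFeatures:
    with h5py.File(path, "r") as f:
        g = f["features"]
        channel_locus = g["channel_locus"][()] if "channel_locus" in g else None
        return TFFeatures(
            values=g["values"][()], frame_times=g["frame_times"][()],
            window=float(g.attrs["window"]), step=float(g.attrs["step"]),
            channel_locus=channel_locus,
        )


def write_mpc(path, mpc: MPCMap) -> None:
    with h5py.File(path, "a") as f:
        if "mpc" in f:
            del f["mpc"]
        g = f.create_group("mpc")
        g.create_dataset("values", data=mpc.values)
        g.create_dataset("shifts", data=mpc.shifts)
        g.create_dataset("degenerate", data=mpc.degenerate)
        g.attrs["n_folds"] = mpc.n_folds
        g.attrs["lam"] = mpc.lam


def read_mpc(path) -> MPCMap:
    with h5py.File(path, "r") as f:
        g = f["mpc"]
        return MPCMap(
            shifts=g["shifts"][()], values=g["values"][()],
            degenerate=g["degenerate"][()].astype(bool),
            n_folds=int(g.attrs["n_folds"]), lam=float(g.attrs["lam"]),
        )


def write_cortical_map_values(path, cmap: CorticalMap) -> None:
    with h5py.File(path, "a") as f:
        if "cortical_map" in f:
            del f["cortical_map"]
        g = f.create_group("cortical_map")
        g.create_dataset("values", data=cmap.values)
        g.create_dataset("times", data=cmap.times)
        g.attrs["source"] = cmap.source


def read_cortical_map_values(path) -> tuple[np.ndarray, np.ndarray, str]:
    """(values, times, source) — the mesh itself lives in OFF + label files."""
    with h5py.File(path, "r") as f:
        g = f["cortical_map"]
        return g["values"][()], g["times"][()], str(g.attrs["source"])


# -- events TSV ---------------------------------------------------------------

def write_events(path, onset_times, labels=None) -> None:
    onset_times = np.asarray(onset_times, dtype=float)
    if labels is None:
        labels = ["stim"] * onset_times.size
    with open(path, "w") as f:
        f.write("onset_s\tlabel\n")
        for t, lab in zip(onset_times, labels):
            f.write(f"{float(t)!r}\t{lab}\n")


def read_events(path) -> tuple[np.ndarray, list[str]]:
    onsets: list[float] = []
    labels: list[str] = []
    with open(path) as f:
        header = f.readline()
        if not header.startswith("onset_s"):
            raise ValueError(f"{path}: missing onset_s header")
        for lineno, line in enumerate(f, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got "
                                 f"{len(parts)}")
            try:
                onsets.append(float(parts[0]))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: bad onset value {parts[0]!r}"
                ) from None
            labels.append(parts[1])
    if not onsets:
        raise ValueError(f"{path}: no onsets")
    return np.asarray(onsets), labels


# -- OFF mesh + label TSV -----------------------------------------------------

def write_mesh(path, mesh: CorticalMesh) -> None:
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{mesh.n_vertices} {mesh.faces.shape[0]} 0\n")
        for v in mesh.vertices:
            f.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for face in mesh.faces:
            f.write(f"3 {int(face[0])} {int(face[1])} {int(face[2])}\n")


def read_mesh(path, labels_path=None) -> CorticalMesh:
    """Read an OFF mesh; region labels come from ``labels_path`` if given."""
    with open(path) as f:
        magic = f.readline().strip()
        if magic != "OFF":
            raise ValueError(f"{path}: not an OFF file (header {magic!r})")
        nv, nf, _ = (int(tok) for tok in f.readline().split())
        verts = np.empty((nv, 3))
        for i in range(nv):
            verts[i] = [float(tok) for tok in f.readline().split()]
        faces = np.empty((nf, 3), dtype=np.int64)
        for i in range(nf):
            toks = f.readline().split()
            if int(toks[0]) != 3:
                raise ValueError(f"{path}: face {i} is not a triangle")
            faces[i] = [int(tok) for tok in toks[1:4]]
    if nf and (faces.min() < 0 or faces.max() >= nv):
        raise ValueError(f"{path}: face index out of range [0, {nv})")
    if labels_path is not None:
        labels = read_labels(labels_path, nv)
    else:
        labels = np.array(["unlabeled"] * nv)
    return CorticalMesh(vertices=verts, faces=faces, region_label=labels)


def write_labels(path, mesh: CorticalMesh) -> None:
    with open(path, "w") as f:
        f.write("vertex_id\tregion\n")
        for i, lab in enumerate(mesh.region_label):
            f.write(f"{i}\t{lab}\n")


def read_labels(path, n_vertices: int) -> np.ndarray:
    labels = np.empty(n_vertices, dtype=object)
    seen = np.zeros(n_vertices, dtype=bool)
    with open(path) as f:
        header = f.readline()
        if not header.startswith("vertex_id"):
            raise ValueError(f"{path}: missing vertex_id header")
        for lineno, line in enumerate(f, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            idx_s, region = line.split("\t")
            idx = int(idx_s)
            if not 0 <= idx < n_vertices:
                raise ValueError(f"{path}:{lineno}: vertex id {idx} out of range")
            labels[idx] = region
            seen[idx] = True
    if not seen.all():
        raise ValueError(f"{path}: {int((~seen).sum())} vertices unlabeled")
    return labels.astype(str)


# -- tabular summaries --------------------------------------------------------

def mpc_long_table(mpc: MPCMap) -> list[tuple[int, float, float]]:
    """Long-format (locus, shift_s, R) rows of an MPC map."""
    return [
        (locus, float(shift), float(mpc.values[locus, si]))
        for locus in range(mpc.n_loci)
        for si, shift in enumerate(mpc.shifts)
    ]


def write_mpc_tsv(path, mpc: MPCMap) -> None:
    with open(path, "w") as f:
        f.write("locus\tshift_s\tR\n")
        for locus, shift, r in mpc_long_table(mpc):
            f.write(f"{locus}\t{shift:.6f}\t{float(r)!r}\n")


def write_region_tsv(path, rts) -> None:
    """Region x time values with significance flags (if computed)."""
    with open(path, "w") as f:
        f.write("region\ttime_s\tvalue\tsignificant\n")
        for ri, region in enumerate(rts.regions):
            for ti, t in enumerate(rts.times):
                flag = (int(rts.significant[ri, ti])
                        if rts.significant is not None else "")
                f.write(f"{region}\t{t:.6f}\t{float(rts.values[ri, ti])!r}\t{flag}\n")


def write_vertex_tsv(path, cmap: CorticalMap, time_index: int) -> None:
    """Per-vertex values of one shift/time slice."""
    with open(path, "w") as f:
        f.write("vertex\tvalue\n")
        for i, v in enumerate(cmap.values[:, time_index]):
            f.write(f"{i}\t{float(v)!r}\n")
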