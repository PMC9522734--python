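"""Readers and writers for the package's file dialects.

All writers are deterministic: keys are emitted in a fixed order and floats
are formatted with 17 significant digits (value-preserving for IEEE doubles),
so identical inputs give byte-identical files.

Dialects
--------
- configurations: CSV with header ``id,x0,...,count``, or multi-frame XYZ
  (frames flattened to 3*N_atoms coordinate vectors, count 1 per frame,
  coincident frames merged by grid rounding);
- graph, quadratic model, response profile: JSON;
- chain trace, node density, autocorrelation: CSV;
- path ensembles: JSON lines, one node sequence per line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cg_graph import CGParams, Configuration, Edge, ManifoldGraph
from .qubo import QuadraticModel
from .response import ResponseProfile

__all__ = [
    "read_configurations",
    "write_configurations",
    "read_graph",
    "write_graph",
    "write_model",
    "read_profile",
    "write_profile",
    "write_chain",
    "read_ensemble",
    "write_ensemble",
    "RunConfig",
    "graph_hash",
]

_F = "{:.17g}".format


def _num(x: float) -> float:
    return float(_F(float(x)))


def read_configurations(path: str | Path, dialect: str = "csv") -> list[Configuration]:
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'xyz'")


def _read_csv(path: Path) -> list[Configuration]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if cols[0] != "id" or cols[-1] != "count":
        raise ValueError(f"{path}: expected header 'id,x0,...,count', got {cols}")
    coord_cols = cols[1:-1]
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = np.asarray([getattr(row, c) for c in coord_cols], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{path}:{row_no}: non-finite coordinate")
        out.append(Configuration(id=int(row.id), coords=vals, count=int(row.count)))
    return out


def _read_xyz(path: Path, merge_decimals: int = 6) -> list[Configuration]:
    """Multi-frame XYZ; each frame becomes one flattened configuration.

    Duplicate frames (identical after rounding coordinates to
    ``merge_decimals``) are merged, accumulating their counts.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n_atoms = int(lines[k].strip())
        except ValueError:
            raise ValueError(f"{path}:{k + 1}: expected an atom count") from None
        block = lines[k + 2 : k + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValueError(f"{path}:{k + 1}: truncated frame")
        coords = []
        for off, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{k + 3 + off}: malformed atom line")
            coords.extend(float(p) for p in parts[1:4])
        frames.append(np.asarray(coords))
        k += 2 + n_atoms
    merged: dict[tuple, tuple[np.ndarray, int]] = {}
    for fr in frames:
        key = tuple(np.round(fr, merge_decimals))
        if key in merged:
            c, n = merged[key]
            merged[key] = (c, n + 1)
        else:
            merged[key] = (fr, 1)
    return [
        Configuration(id=i, coords=c, count=n)
        for i, (c, n) in enumerate(merged.values())
    ]


def write_configurations(configs: list[Configuration], path: str | Path) -> None:
    d = len(configs[0].coords)
    header = ["id"] + [f"x{k}" for k in range(d)] + ["count"]
    rows = [
        ",".join([str(c.id)] + [_F(v) for v in c.coords] + [str(c.count)])
        for c in configs
    ]
    Path(path).write_text(",".join(header) + "\n" + "\n".join(rows) + "\n")


def _graph_dict(graph: ManifoldGraph) -> dict:
    p = graph.params
    return {
        "nodes": [
            {
                "id": c.id,
                "coords": [_num(v) for v in c.coords],
                "count": c.count,
                "Vcg": _num(graph.V_cg[k]),
            }
            for k, c in enumerate(graph.configurations)
        ],
        "edges": [
            {
                "i": e.i, "j": e.j, "dist2": _num(e.dist2),
                "w_ij": _num(e.w_ij), "w_ji": _num(e.w_ji), "w_sym": _num(e.w_sym),
            }
            for e in sorted(graph.edges, key=lambda e: (e.i, e.j))
        ],
        "params": {
            "m": _num(p.mass), "dt": _num(p.dt), "sigma": _num(p.sigma),
            "Dcg": _num(p.D_cg), "kBT": _num(p.kBT),
        },
    }


def write_graph(graph: ManifoldGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_graph_dict(graph), indent=1) + "\n")


def read_graph(path: str | Path) -> ManifoldGraph:
    d = json.loads(Path(path).read_text())
    p = d["params"]
    params = CGParams(mass=p["m"], dt=p["dt"], sigma=p["sigma"], kBT=p["kBT"])
    configs = [
        Configuration(id=n["id"], coords=np.asarray(n["coords"]), count=n["count"])
        for n in d["nodes"]
    ]
    V = np.asarray([n["Vcg"] for n in d["nodes"]])
    edges = [
        Edge(i=e["i"], j=e["j"], dist2=e["dist2"], w_ij=e["w_ij"],
             w_ji=e["w_ji"], w_sym=e["w_sym"])
        for e in d["edges"]
    ]
    return ManifoldGraph(configurations=configs, V_cg=V, edges=edges, params=params)


def graph_hash(graph: ManifoldGraph) -> str:
    payload = json.dumps(_graph_dict(graph), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _var_key(var) -> str:
    kind, key = var
    return f"n:{key}" if kind == "n" else f"e:{key[0]}-{key[1]}"


def write_model(
    model: QuadraticModel,
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    d = {
        "variables": [_var_key(v) for v in model.variables],
        "linear": {_var_key(v): _num(a) for v, a in sorted(model.linear.items(), key=lambda kv: _var_key(kv[0]))},
        "quadratic": {
            f"{_var_key(u)}|{_var_key(v)}": _num(q)
            for (u, v), q in sorted(model.quadratic.items(), key=lambda kv: (_var_key(kv[0][0]), _var_key(kv[0][1])))
        },
        "offset": _num(model.offset),
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(d, indent=1) + "\n")


def write_profile(profile: ResponseProfile, path: str | Path) -> None:
    d = {
        "floor": _num(profile.floor),
        "entries": [
            {
                "t_sweep": _num(t), "E_bar": _num(e), "Delta": _num(dl),
                "n": int(n), "valid_fraction": _num(vf),
            }
            for t, e, dl, n, vf in zip(
                profile.t_grid, profile.E_bar, profile.Delta, profile.n,
                profile.valid_fraction,
            )
        ],
    }
    Path(path).write_text(json.dumps(d, indent=1) + "\n")


def read_profile(path: str | Path) -> ResponseProfile:
    d = json.loads(Path(path).read_text())
    ent = d["entries"]
    return ResponseProfile(
        t_grid=[e["t_sweep"] for e in ent],
        E_bar=[e["E_bar"] for e in ent],
        Delta=[e["Delta"] for e in ent],
        n=[e["n"] for e in ent],
        valid_fraction=[e["valid_fraction"] for e in ent],
        floor=d["floor"],
    )


def write_chain(record, path: str | Path) -> None:
    df = record.to_dataframe()
    cols = ["step", "t_sweep", "S", "t_proposed", "S_proposed", "accepted", "valid", "seed"]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def write_ensemble(paths, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in paths:
            fh.write(json.dumps({"nodes": list(p.nodes), "S": _num(p.action)}) + "\n")


def read_ensemble(path: str | Path) -> list[dict]:
    return [json.loads(ln) for ln in Path(path).read_text().splitlines() if ln.strip()]


_CONFIG_KEYS = {
    # coarse-grained theory
    "mass": 1.0, "dt": 1.0, "sigma": None, "kBT": 1.0,
    # adjacency
    "knn_k": 6, "d_max_sigmas": 3.0,
    # encoding
    "alpha": None,
    # annealer
    "beta_start": 0.1, "beta_end": 10.0, "sweeps_per_second": 10.0,
    # sweep-time dynamics
    "t0": 150.0, "k": 2e-4, "delta_t": 50.0, "t_min": None, "t_max": None,
    # chain
    "n_steps": 1000, "seed": 0, "burn_in": 0.1,
}


class RunConfig(dict):
    """Flat ``key: value`` run configuration; unknown keys are rejected."""

    def __init__(self, **kwargs):
        unknown = set(kwargs) - set(_CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_CONFIG_KEYS)
        merged.update(kwargs)
        super().__init__(merged)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dict(sorted(self.items())), default_flow_style=False)
        )
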