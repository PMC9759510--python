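"""Profile readers/writers and run manifests.

Every profile (travelling wave, outer solution, composite) is stored as a
plain CSV of columns ``z, W, U, J, M`` plus a JSON sidecar (same stem,
``.json``) carrying the parameters, period, speed and solver residual, so
that results are diffable and reusable outside Python.  Floats are written
with full round-trip precision (``repr``), so write-then-read restores the
arrays bit-for-bit.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import Params
from .outer import OuterSolution
from .waves import WaveProfile

__all__ = ["write_profile", "read_profile", "write_outer", "read_outer",
           "RunManifest"]

_FLOAT_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_profile(profile: WaveProfile, path) -> Path:
    """Write a wave profile as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({
        "z": profile.z_mesh, "W": profile.W, "U": profile.U,
        "J": profile.J, "M": profile.M, "s": profile.s_mesh,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "kind": "wave",
        "params": profile.params.to_dict(),
        "L": profile.L,
        "c": profile.c,
        "residual": profile.residual,
        "version": __version__,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_profile(path) -> WaveProfile:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    L = float(meta["L"])
    s_mesh = (df["s"].to_numpy() if "s" in df.columns
              else df["z"].to_numpy() / L)
    return WaveProfile(
        s_mesh=s_mesh,
        W=df["W"].to_numpy(), U=df["U"].to_numpy(),
        J=df["J"].to_numpy(), M=df["M"].to_numpy(),
        L=L, c=float(meta["c"]),
        params=Params.from_dict(meta["params"]),
        residual=float(meta.get("residual", float("nan"))),
    )


def write_outer(sol: OuterSolution, path) -> Path:
    """Write an outer solution (U included as a derived column)."""
    path = Path(path)
    df = pd.DataFrame({
        "z": sol.z_mesh, "W": sol.W_out, "U": sol.U_out,
        "J": sol.J_out, "M": sol.M_out,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "kind": "outer",
        "params": sol.params.to_dict(),
        "L": sol.L,
        "residual": sol.residual,
        "version": __version__,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_outer(path) -> OuterSolution:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    return OuterSolution(
        z_mesh=df["z"].to_numpy(),
        W_out=df["W"].to_numpy(), J_out=df["J"].to_numpy(),
        M_out=df["M"].to_numpy(),
        L=float(meta["L"]),
        params=Params.from_dict(meta["params"]),
        residual=float(meta.get("residual", float("nan"))),
    )


class RunManifest:
    """Reproducibility record written alongside every CLI run."""

    def __init__(self, command: str, config: dict, *, seed=None,
                 tolerances=None):
        self.data = {
            "command": command,
            "config": config,
            "seed": seed,
            "tolerances": tolerances or {},
            "tool_version": __version__,
            "python": platform.python_version(),
            "outputs": [],
        }
        self._t0 = time.time()

    def add_output(self, path) -> None:
        self.data["outputs"].append(str(path))

    def add(self, **kw) -> None:
        self.data.update(kw)

    def write(self, path) -> Path:
        path = Path(path)
        self.data["wall_time_s"] = round(time.time() - self._t0, 3)
        path.write_text(json.dumps(self.data, indent=2, default=_jsonable)
                        + "\n")
        return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
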