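"""HDF5 round-trips for the package's data types, plus run manifests.

Schemas
-------
ActivityTensor: datasets ``rates`` (K x T x N), ``time`` (T), ``condition``
(K, int, 0=left/1=right), ``outcome`` (K, int, 1=hit/0=miss), optional
``trial_bias`` and ``lick_rate``; attributes ``tone_windows``,
``go_window``, ``dt``, ``seed``.

LowRankNetwork (+ InputSpec): datasets ``U``, ``A``, ``rmax`` and the input
vectors; attributes ``tau``, ``n_coding`` and the window schedule.

CodingBasis: dataset ``vectors``; window attributes and a ``source`` tag.

TwoAreaNetwork: a ``cortex`` group with the network schema plus thalamic
and bottleneck datasets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .coding import CodingBasis
from .network import InputSpec, LowRankNetwork
from .synthetic import ActivityTensor
from .thalamocortical import TwoAreaNetwork

__all__ = [
    "save_tensor",
    "load_tensor",
    "save_network",
    "load_network",
    "save_basis",
    "load_basis",
    "save_two_area",
    "load_two_area",
    "write_manifest",
]


def _maybe(group: h5py.Group, name: str, arr) -> None:
    if arr is not None:
        group.create_dataset(name, data=np.asarray(arr))


def _get(group: h5py.Group, name: str):
    return np.asarray(group[name]) if name in group else None


def save_tensor(path: str | Path, tensor: ActivityTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=tensor.rates)
        f.create_dataset("time", data=tensor.time)
        f.create_dataset("condition", data=tensor.condition.astype(np.int64))
        f.create_dataset("outcome", data=tensor.outcome.astype(np.int64))
        _maybe(f, "trial_bias", tensor.trial_bias)
        _maybe(f, "lick_rate", tensor.lick_rate)
        f.attrs["tone_windows"] = np.asarray(tensor.tone_windows)
        f.attrs["go_window"] = np.asarray(tensor.go_window)
        f.attrs["dt"] = tensor.dt
        f.attrs["seed"] = tensor.seed


def load_tensor(path: str | Path) -> ActivityTensor:
    with h5py.File(path, "r") as f:
        for key in ("rates", "time", "condition", "outcome"):
            if key not in f:
                raise ValueError(f"corrupted activity file: missing dataset {key!r}")
        return ActivityTensor(
            rates=np.asarray(f["rates"]),
            time=np.asarray(f["time"]),
            condition=np.asarray(f["condition"]),
            outcome=np.asarray(f["outcome"]),
            trial_bias=_get(f, "trial_bias"),
            lick_rate=_get(f, "lick_rate"),
            tone_windows=tuple(map(tuple, f.attrs["tone_windows"])),
            go_window=tuple(f.attrs["go_window"]),
            dt=float(f.attrs["dt"]),
            seed=int(f.attrs["seed"]),
        )


def _save_network_group(g: h5py.Group, net: LowRankNetwork, spec: InputSpec | None):
    g.create_dataset("U", data=net.U)
    g.create_dataset("A", data=net.A)
    g.create_dataset("rmax", data=net.rmax)
    g.attrs["tau"] = net.tau
    g.attrs["n_coding"] = net.n_coding
    if spec is not None:
        g.create_dataset("I_low", data=spec.I_low)
        g.create_dataset("I_high", data=spec.I_high)
        g.create_dataset("I_go", data=spec.I_go)
        _maybe(g, "I_lick_left", spec.I_lick_left)
        _maybe(g, "I_lick_right", spec.I_lick_right)
        _maybe(g, "lick_times", spec.lick_times)
        _maybe(g, "lick_rates", spec.lick_rates)
        g.attrs["tone_windows"] = np.asarray(spec.tone_windows)
        g.attrs["go_window"] = np.asarray(spec.go_window)


def _load_network_group(g: h5py.Group) -> tuple[LowRankNetwork, InputSpec | None]:
    for key in ("U", "A", "rmax"):
        if key not in g:
            raise ValueError(f"corrupted network file: missing dataset {key!r}")
    net = LowRankNetwork(
        U=np.asarray(g["U"]),
        A=np.asarray(g["A"]),
        rmax=np.asarray(g["rmax"]),
        tau=float(g.attrs["tau"]),
        n_coding=int(g.attrs["n_coding"]),
    )
    spec = None
    if "I_low" in g:
        spec = InputSpec(
            I_low=np.asarray(g["I_low"]),
            I_high=np.asarray(g["I_high"]),
            I_go=np.asarray(g["I_go"]),
            I_lick_left=_get(g, "I_lick_left"),
            I_lick_right=_get(g, "I_lick_right"),
            lick_times=_get(g, "lick_times"),
            lick_rates=_get(g, "lick_rates"),
            tone_windows=tuple(map(tuple, g.attrs["tone_windows"])),
            go_window=tuple(g.attrs["go_window"]),
        )
    return net, spec


def save_network(
    path: str | Path, net: LowRankNetwork, spec: InputSpec | None = None
) -> None:
    with h5py.File(path, "w") as f:
        _save_network_group(f, net, spec)


def load_network(path: str | Path) -> tuple[LowRankNetwork, InputSpec | None]:
    with h5py.File(path, "r") as f:
        return _load_network_group(f)


def save_basis(path: str | Path, basis: CodingBasis) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("vectors", data=basis.vectors)
        f.attrs["source"] = basis.source
        for name, window in basis.windows.items():
            f.attrs[f"window_{name}"] = np.asarray(window)


def load_basis(path: str | Path) -> CodingBasis:
    with h5py.File(path, "r") as f:
        if "vectors" not in f:
            raise ValueError("corrupted basis file: missing dataset 'vectors'")
        windows = {
            k[len("window_"):]: tuple(v)
            for k, v in f.attrs.items()
            if k.startswith("window_")
        }
        return CodingBasis(
            vectors=np.asarray(f["vectors"]),
            windows=windows,
            source=str(f.attrs["source"]),
        )


def save_two_area(path: str | Path, net: TwoAreaNetwork) -> None:
    with h5py.File(path, "w") as f:
        cx = f.create_group("cortex")
        _save_network_group(cx, net.cortex, net.spec_cortex)
        f.create_dataset("U_th", data=net.U_th)
        f.create_dataset("rmax_th", data=net.rmax_th)
        for name in ("ct_pre", "B_ct", "ct_post", "tc_pre", "B_tc", "tc_post"):
            f.create_dataset(name, data=getattr(net, name))
        f.create_dataset("I_go_th", data=net.I_go_th)
        f.attrs["go_window"] = np.asarray(net.go_window)


def load_two_area(path: str | Path) -> TwoAreaNetwork:
    with h5py.File(path, "r") as f:
        cortex, spec = _load_network_group(f["cortex"])
        return TwoAreaNetwork(
            cortex=cortex,
            U_th=np.asarray(f["U_th"]),
            rmax_th=np.asarray(f["rmax_th"]),
            ct_pre=np.asarray(f["ct_pre"]),
            B_ct=np.asarray(f["B_ct"]),
            ct_post=np.asarray(f["ct_post"]),
            tc_pre=np.asarray(f["tc_pre"]),
            B_tc=np.asarray(f["B_tc"]),
            tc_post=np.asarray(f["tc_post"]),
            spec_cortex=spec,
            I_go_th=np.asarray(f["I_go_th"]),
            go_window=tuple(f.attrs["go_window"]),
        )


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> dict:
    """JSON manifest of a run: config, seeds, versions, and file hashes."""
    import latentloop

    def _hash(p) -> str | None:
        p = Path(p)
        if not p.exists():
            return None
        return hashlib.sha256(p.read_bytes()).hexdigest()[:16]

    manifest = {
        "command": command,
        "config": config,
        "versions": {
            "latentloop": latentloop.__version__,
            "numpy": np.__version__,
        },
        "inputs": {str(p): _hash(p) for p in inputs},
        "outputs": {str(p): _hash(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
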