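"""Multi-shell, multi-diffusion-time PGSE acquisition protocols.

A protocol is an ordered list of shells, each defined by the diffusion
weighting ``b`` (ms/µm²), the gradient pulse separation ``Delta`` (ms), the
gradient pulse duration ``delta`` (ms) and the number of gradient
directions.  For a rectangular pulsed-gradient spin-echo (PGSE) sequence the
effective diffusion time is ``t_d = Delta - delta/3`` and the wave number is
``q = sqrt(b / t_d)`` (1/µm), so that ``b = q² t_d``.

Shell order is preserved exactly as loaded: signal curves and fits index
into it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Shell",
    "AcquisitionProtocol",
    "ProtocolError",
    "load_protocol",
    "load_fsl_protocol",
    "save_protocol",
    "default_clinical_protocol",
    "count_volumes",
    "with_pulse_width",
]

#: values above this are interpreted as s/mm² and divided by 1000
_B_UNIT_THRESHOLD = 100.0


class ProtocolError(ValueError):
    """Raised when an acquisition table or protocol fails validation."""


@dataclass(frozen=True)
class Shell:
    """One acquisition shell: unique (b, Delta, delta) with its directions.

    Parameters
    ----------
    b : float
        Diffusion weighting in ms/µm².
    Delta : float
        Gradient pulse separation Δ in ms.
    delta : float
        Gradient pulse duration δ in ms.
    n_dirs : int
        Number of gradient directions (volumes) in the shell.
    """

    b: float
    Delta: float
    delta: float
    n_dirs: int = 1
    directions: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.b) and self.b >= 0):
            raise ProtocolError(f"b must be >= 0, got {self.b}")
        if not (self.Delta > 0):
            raise ProtocolError(f"Delta must be > 0, got {self.Delta}")
        if not (0 < self.delta <= self.Delta):
            raise ProtocolError(
                f"delta must satisfy 0 < delta <= Delta, got delta={self.delta}, Delta={self.Delta}"
            )
        if self.n_dirs < 1:
            raise ProtocolError(f"n_dirs must be >= 1, got {self.n_dirs}")
        if not self.t_d > 0:
            raise ProtocolError("derived t_d = Delta - delta/3 must be > 0")

    @property
    def is_b0(self) -> bool:
        return self.b == 0.0

    @property
    def t_d(self) -> float:
        """Effective diffusion time Δ − δ/3 (ms)."""
        return self.Delta - self.delta / 3.0

    @property
    def q(self) -> float:
        """Wave number sqrt(b / t_d) in 1/µm; 0 for b = 0."""
        return math.sqrt(self.b / self.t_d)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered collection of shells defining the signal axis."""

    shells: tuple[Shell, ...]
    name: str = ""

    def __post_init__(self) -> None:
        shells = tuple(self.shells)
        object.__setattr__(self, "shells", shells)
        if not shells:
            raise ProtocolError("protocol needs at least one shell")
        # b0-only protocols are allowed (noise-estimation subsets); fitting
        # enforces a minimum number of b > 0 points separately
        deltas_by_Delta: dict[float, float] = {}
        for s in shells:
            prev = deltas_by_Delta.setdefault(s.Delta, s.delta)
            if prev != s.delta:
                raise ProtocolError(
                    f"mixed pulse durations within Delta={s.Delta}: {prev} vs {s.delta}"
                )

    def __len__(self) -> int:
        return len(self.shells)

    def __iter__(self):
        return iter(self.shells)

    @property
    def b(self) -> np.ndarray:
        return np.array([s.b for s in self.shells])

    @property
    def Delta(self) -> np.ndarray:
        return np.array([s.Delta for s in self.shells])

    @property
    def delta(self) -> np.ndarray:
        return np.array([s.delta for s in self.shells])

    @property
    def t_d(self) -> np.ndarray:
        return np.array([s.t_d for s in self.shells])

    @property
    def q(self) -> np.ndarray:
        return np.array([s.q for s in self.shells])

    @property
    def b0_mask(self) -> np.ndarray:
        return np.array([s.is_b0 for s in self.shells])

    @property
    def dwi_mask(self) -> np.ndarray:
        """Boolean mask of shells with b > 0 (the fitted points)."""
        return ~self.b0_mask

    def volume_table(self) -> pd.DataFrame:
        """Per-volume expansion: one row per acquired volume, in shell order.

        Columns ``b, Delta, delta, gx, gy, gz, shell_index``.  b = 0 shells
        expand to ``n_dirs`` rows with zero gradient direction.
        """
        rows = []
        for i, s in enumerate(self.shells):
            dirs = s.directions if len(s.directions) == s.n_dirs else _fibonacci_sphere(s.n_dirs)
            if s.is_b0:
                dirs = [(0.0, 0.0, 0.0)] * s.n_dirs
            for g in dirs:
                rows.append((s.b, s.Delta, s.delta, g[0], g[1], g[2], i))
        return pd.DataFrame(rows, columns=["b", "Delta", "delta", "gx", "gy", "gz", "shell_index"])

    def fingerprint(self) -> tuple:
        """Hashable identity used to cache per-protocol computations."""
        return tuple((s.b, s.Delta, s.delta) for s in self.shells)


def _fibonacci_sphere(n: int) -> list[tuple[float, float, float]]:
    """Deterministic quasi-uniform unit directions (placeholder scheme).

    The powder-average pipeline only uses direction counts; explicit vectors
    are kept so acquisition tables round-trip.
    """
    if n == 1:
        return [(0.0, 0.0, 1.0)]
    ga = math.pi * (3.0 - math.sqrt(5.0))
    out = []
    for i in range(n):
        z = 1.0 - 2.0 * i / (n - 1)
        r = math.sqrt(max(0.0, 1.0 - z * z))
        out.append((r * math.cos(ga * i), r * math.sin(ga * i), z))
    return out


def _normalize_b(b: np.ndarray, unit: str | None) -> np.ndarray:
    """Convert b to ms/µm²; autodetect s/mm² when no unit is declared."""
    b = np.asarray(b, dtype=float)
    if unit is not None:
        unit = unit.strip().lower().replace(" ", "")
        if unit in {"s/mm2", "s/mm^2", "s/mm²"}:
            return b / 1000.0
        if unit in {"ms/um2", "ms/µm2", "ms/um^2", "ms/µm²", "ms/µm^2"}:
            return b
        raise ProtocolError(f"unknown b unit {unit!r}")
    if np.any(b > _B_UNIT_THRESHOLD):
        return b / 1000.0
    return b


def load_protocol(path: str | Path, name: str | None = None) -> AcquisitionProtocol:
    """Read a per-volume acquisition TSV into a validated protocol.

    The table has one row per volume with columns ``b, Delta, delta`` and
    optionally ``gx, gy, gz``.  Units may be declared in a leading comment
    line ``# b_unit: s/mm2`` (or ``ms/um2``); otherwise b-values above 100
    are treated as s/mm² and divided by 1000.  Rows are collapsed into
    shells by unique (b, Delta, delta) in first-appearance order.
    """
    path = Path(path)
    unit = None
    with open(path) as fh:
        head = fh.readline()
        if head.startswith("#") and "b_unit" in head:
            unit = head.split(":", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("b", "Delta", "delta"):
        if col not in df.columns:
            raise ProtocolError(f"acquisition table {path} is missing column {col!r}")
    if not all(np.issubdtype(df[col].dtype, np.number) for col in ("b", "Delta", "delta")):
        raise ProtocolError(f"non-numeric values in acquisition table {path}")
    df = df.copy()
    df["b"] = _normalize_b(df["b"].to_numpy(), unit)
    has_dirs = all(c in df.columns for c in ("gx", "gy", "gz"))

    shells: list[Shell] = []
    seen: dict[tuple, int] = {}
    groups: dict[tuple, list] = {}
    for _, row in df.iterrows():
        key = (row["b"], row["Delta"], row["delta"])
        g = (row["gx"], row["gy"], row["gz"]) if has_dirs else None
        groups.setdefault(key, []).append(g)
        seen.setdefault(key, len(seen))
    for key, _ in sorted(seen.items(), key=lambda kv: kv[1]):
        dirs = groups[key]
        directions = tuple(d for d in dirs if d is not None)
        shells.append(
            Shell(
                b=key[0],
                Delta=key[1],
                delta=key[2],
                n_dirs=len(dirs),
                directions=directions if len(directions) == len(dirs) else (),
            )
        )
    return AcquisitionProtocol(tuple(shells), name=name or path.stem)


def load_fsl_protocol(
    bval: str | Path, bvec: str | Path, timing: str | Path, name: str = ""
) -> AcquisitionProtocol:
    """Build a protocol from FSL-dialect bval/bvec plus a per-volume Δ/δ TSV.

    bval/bvec cannot carry pulse timing, so ``timing`` must be a TSV with
    per-volume columns ``Delta`` and ``delta`` in ms (same volume order).
    """
    bvals = np.loadtxt(bval, ndmin=2).ravel()
    bvecs = np.loadtxt(bvec, ndmin=2)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    tdf = pd.read_csv(timing, sep="\t", comment="#")
    if len(tdf) != len(bvals):
        raise ProtocolError(
            f"timing table has {len(tdf)} rows but bval lists {len(bvals)} volumes"
        )
    df = pd.DataFrame(
        {
            "b": _normalize_b(bvals, None),
            "Delta": tdf["Delta"].to_numpy(),
            "delta": tdf["delta"].to_numpy(),
            "gx": bvecs[:, 0],
            "gy": bvecs[:, 1],
            "gz": bvecs[:, 2],
        }
    )
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        df.to_csv(fh, sep="\t", index=False)
        tmp = fh.name
    try:
        proto = load_protocol(tmp, name=name)
    finally:
        Path(tmp).unlink(missing_ok=True)
    return proto


def save_protocol(protocol: AcquisitionProtocol, path: str | Path) -> None:
    """Write a protocol as a per-volume TSV (inverse of :func:`load_protocol`)."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        with open(path, "w") as fh:
            yaml.safe_dump(protocol_to_dict(protocol), fh, sort_keys=False)
        return
    df = protocol.volume_table().drop(columns="shell_index")
    with open(path, "w") as fh:
        fh.write("# b_unit: ms/um2\n")
        df.to_csv(fh, sep="\t", index=False)


def protocol_to_dict(protocol: AcquisitionProtocol) -> dict:
    """Plain-dict form for YAML provenance records."""
    return {
        "name": protocol.name,
        "shells": [
            {"b": s.b, "Delta": s.Delta, "delta": s.delta, "n_dirs": s.n_dirs}
            for s in protocol.shells
        ],
    }


def protocol_from_dict(d: dict) -> AcquisitionProtocol:
    shells = tuple(
        Shell(b=s["b"], Delta=s["Delta"], delta=s["delta"], n_dirs=s["n_dirs"])
        for s in d["shells"]
    )
    return AcquisitionProtocol(shells, name=d.get("name", ""))


def default_clinical_protocol() -> AcquisitionProtocol:
    """The built-in clinical 3T protocol used throughout this package.

    b = {1, 2} ms/µm² at Δ = {28.3, 36.0} ms; b = {1, 2, 3.2, 4.44} at
    Δ = 45.0 ms; b = {1, 2, 3.2, 5} at Δ = {55.0, 65.0} ms; δ = 16.5 ms
    everywhere; 20 directions per b > 0 shell and one b = 0 volume per Δ.
    That is 21 shells (16 with b > 0) and 325 volumes in total.
    """
    delta = 16.5
    plan = {
        28.3: [1.0, 2.0],
        36.0: [1.0, 2.0],
        45.0: [1.0, 2.0, 3.2, 4.44],
        55.0: [1.0, 2.0, 3.2, 5.0],
        65.0: [1.0, 2.0, 3.2, 5.0],
    }
    shells: list[Shell] = []
    for Delta in sorted(plan):
        shells.append(Shell(b=0.0, Delta=Delta, delta=delta, n_dirs=1))
        for b in plan[Delta]:
            shells.append(Shell(b=b, Delta=Delta, delta=delta, n_dirs=20))
    return AcquisitionProtocol(tuple(shells), name="clinical-3T-multi-td")


def count_volumes(protocol: AcquisitionProtocol) -> int:
    """Total diffusion volumes: Σ n_dirs over shells (one per b = 0 volume).

    Reversed-phase-encode calibration volumes are not part of the protocol
    and are therefore never counted.
    """
    return sum(s.n_dirs for s in protocol.shells)


def with_pulse_width(protocol: AcquisitionProtocol, delta: float) -> AcquisitionProtocol:
    """Copy of ``protocol`` with every shell's δ replaced (b, Δ unchanged).

    Used by the noise-propagation study to contrast wide (16.5 ms) and
    narrow (4 ms) gradient pulses under identical b and Δ sampling.
    """
    shells = tuple(replace(s, delta=delta) for s in protocol.shells)
    return AcquisitionProtocol(shells, name=f"{protocol.name}-delta{delta:g}")


def select_volumes(
    protocol: AcquisitionProtocol,
    b_max: float | None = None,
    b_values: Sequence[float] | None = None,
) -> AcquisitionProtocol:
    """Sub-protocol keeping shells by b-value (e.g. the low-b subset used
    for noise estimation).  Shell order is preserved."""
    keep = []
    for s in protocol.shells:
        if b_max is not None and s.b > b_max:
            continue
        if b_values is not None and not any(abs(s.b - b) < 1e-9 for b in b_values):
            continue
        keep.append(s)
    return AcquisitionProtocol(tuple(keep), name=f"{protocol.name}-subset")
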