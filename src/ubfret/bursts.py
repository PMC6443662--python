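"""Burst-wise extraction of FRET efficiencies from photon time traces.

Diffusing molecules crossing the confocal volume produce photon bursts on
top of a dim background.  The pipeline is: (1) bin raw photon arrival times
into fixed-width bins (1 ms by default); (2) find maximal runs of
consecutive bins whose summed donor-excitation counts (donor + acceptor
emission) reach a per-bin threshold — each run is one burst; (3) discard
bursts lacking acceptor-excitation photons when a PIE (pulsed interleaved
excitation) channel is present, which removes donor-only and
acceptor-bleached molecules; (4) compute the per-burst proximity ratio

    E = n_A / (n_A + γ·n_D)

with detection-correction factor γ = 1 by default (uncorrected proximity
ratio — no gamma was calibrated here, and this is stated rather than
hidden).

Bins are half-open ``[k·w, (k+1)·w)`` with 0-based indices throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhotonTrace",
    "BurstConfig",
    "Burst",
    "bin_trace",
    "detect_bursts",
    "burst_efficiency",
    "bursts_to_table",
]


@dataclass
class PhotonTrace:
    """Binned two/three-channel photon counts.

    ``donor`` and ``acceptor`` are emission counts under donor excitation;
    ``aex_acceptor`` is the acceptor-emission channel under direct acceptor
    excitation (the PIE channel), optional.
    """

    bin_width: float
    donor: np.ndarray
    acceptor: np.ndarray
    aex_acceptor: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        self.donor = _as_counts(self.donor, "donor")
        self.acceptor = _as_counts(self.acceptor, "acceptor")
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor channels differ in length")
        if self.aex_acceptor is not None:
            self.aex_acceptor = _as_counts(self.aex_acceptor, "aex_acceptor")
            if self.aex_acceptor.shape != self.donor.shape:
                raise ValueError("aex_acceptor channel differs in length")

    @property
    def n_bins(self) -> int:
        return int(self.donor.size)


def _as_counts(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 1:
        raise ValueError(f"{name} channel must be 1-D")
    if np.any(arr < 0):
        raise ValueError(f"{name} counts must be nonnegative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{name} counts must be integers")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class BurstConfig:
    """Burst search parameters.

    ``threshold`` is the per-bin count gate on donor+acceptor emission
    (typical working range 3–5 counts/bin, up to 10 under high background);
    ``min_bins`` discards runs shorter than this; ``pie_min_aex`` is the
    minimum acceptor-excitation count for a burst to be kept when a PIE
    channel exists; ``gamma`` is the detection-correction factor.
    """

    threshold: int = 4
    min_bins: int = 1
    pie_min_aex: int = 1
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class Burst:
    """One detected burst; bin indices are inclusive on both ends."""

    start_bin: int
    end_bin: int
    n_donor: int
    n_acceptor: int
    n_aex: int
    efficiency: float

    def __post_init__(self) -> None:
        if self.end_bin < self.start_bin:
            raise ValueError("end_bin before start_bin")


def bin_trace(
    timestamps: dict[str, np.ndarray],
    bin_width: float,
    n_bins: int | None = None,
) -> PhotonTrace:
    """Bin per-channel photon arrival times (seconds) into counts per bin.

    ``timestamps`` maps channel names (``"donor"``, ``"acceptor"``, and
    optionally ``"aex_acceptor"``) to sorted nonnegative arrival times.
    Bins are half-open; photon counts are conserved exactly.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    known = {"donor", "acceptor", "aex_acceptor"}
    unknown = set(timestamps) - known
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    for name in ("donor", "acceptor"):
        if name not in timestamps:
            raise ValueError(f"missing required channel {name!r}")

    arrays = {}
    max_time = 0.0
    for name, ts in timestamps.items():
        ts = np.asarray(ts, dtype=float)
        if ts.size and np.any(ts < 0):
            raise ValueError(f"{name}: negative timestamps")
        if ts.size and np.any(np.diff(ts) < 0):
            raise ValueError(f"{name}: timestamps must be sorted")
        arrays[name] = ts
        if ts.size:
            max_time = max(max_time, float(ts[-1]))
    if n_bins is None:
        n_bins = int(np.floor(max_time / bin_width)) + 1 if max_time > 0 else 1

    channels = {}
    for name, ts in arrays.items():
        idx = np.floor(ts / bin_width).astype(np.int64)
        channels[name] = np.bincount(idx, minlength=n_bins)
    return PhotonTrace(
        bin_width=bin_width,
        donor=channels["donor"],
        acceptor=channels["acceptor"],
        aex_acceptor=channels.get("aex_acceptor"),
    )


def burst_efficiency(n_donor: int, n_acceptor: int, gamma: float = 1.0) -> float:
    """Proximity-ratio efficiency n_A / (n_A + γ·n_D); rejects empty bursts."""
    if n_donor < 0 or n_acceptor < 0:
        raise ValueError("photon counts must be nonnegative")
    if n_donor + n_acceptor == 0:
        raise ValueError("burst has zero photons")
    return n_acceptor / (n_acceptor + gamma * n_donor)


def detect_bursts(trace: PhotonTrace, cfg: BurstConfig = BurstConfig()) -> list[Burst]:
    """Find bursts as maximal runs of bins with donor+acceptor counts at or
    above the threshold; apply the minimum-length and PIE gates."""
    total = trace.donor + trace.acceptor
    mask = total >= cfg.threshold
    if not mask.any():
        return []
    # run boundaries from the padded difference of the boolean mask
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    bursts: list[Burst] = []
    for s, e in zip(starts, ends):
        if e - s + 1 < cfg.min_bins:
            continue
        n_d = int(trace.donor[s : e + 1].sum())
        n_a = int(trace.acceptor[s : e + 1].sum())
        n_x = int(trace.aex_acceptor[s : e + 1].sum()) if trace.aex_acceptor is not None else 0
        if trace.aex_acceptor is not None and n_x < cfg.pie_min_aex:
            continue
        bursts.append(
            Burst(
                start_bin=int(s),
                end_bin=int(e),
                n_donor=n_d,
                n_acceptor=n_a,
                n_aex=n_x,
                efficiency=burst_efficiency(n_d, n_a, cfg.gamma),
            )
        )
    return bursts


def bursts_to_table(bursts: list[Burst]) -> pd.DataFrame:
    """Burst list as a DataFrame (one row per burst)."""
    return pd.DataFrame(
        [
            {
                "start_bin": b.start_bin,
                "end_bin": b.end_bin,
                "n_donor": b.n_donor,
                "n_acceptor": b.n_acceptor,
                "n_aex": b.n_aex,
                "efficiency": b.efficiency,
            }
            for b in bursts
        ],
        columns=["start_bin", "end_bin", "n_donor", "n_acceptor", "n_aex", "efficiency"],
    )
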