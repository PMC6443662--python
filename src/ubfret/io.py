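"""TSV input/output.

All tables travel as tab-separated text with ``#``-prefixed header comments
recording provenance (generator parameters, seed, column meanings), so any
file is self-describing and diffable.  Photon traces use the 4-column
layout (bin_index, donor_counts, acceptor_counts, aex_acceptor_counts).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bursts import PhotonTrace

__all__ = [
    "write_table",
    "read_table",
    "write_trace",
    "read_trace",
    "read_titration_table",
]


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a DataFrame as TSV with ``# key = value`` header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (params or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_trace(trace: PhotonTrace, path: str | Path, params: dict | None = None) -> None:
    """Photon trace as 4-column TSV; a missing PIE channel is written as 0."""
    aex = trace.aex_acceptor if trace.aex_acceptor is not None else np.zeros_like(trace.donor)
    df = pd.DataFrame(
        {
            "bin_index": np.arange(trace.n_bins),
            "donor_counts": trace.donor,
            "acceptor_counts": trace.acceptor,
            "aex_acceptor_counts": aex,
        }
    )
    meta = {"bin_width": trace.bin_width}
    meta.update(params or {})
    write_table(df, path, meta)


def read_trace(path: str | Path, bin_width: float | None = None) -> PhotonTrace:
    """Read a 4-column trace TSV; ``bin_width`` falls back to the header
    comment, then to 1 ms."""
    if bin_width is None:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "bin_width" in line:
                    bin_width = float(line.split("=")[1])
        if bin_width is None:
            bin_width = 0.001
    df = read_table(path)
    aex = df["aex_acceptor_counts"].to_numpy() if "aex_acceptor_counts" in df else None
    if aex is not None and not aex.any():
        aex = None
    return PhotonTrace(
        bin_width=bin_width,
        donor=df["donor_counts"].to_numpy(),
        acceptor=df["acceptor_counts"].to_numpy(),
        aex_acceptor=aex,
    )


def read_titration_table(path: str | Path, c_diub, baseline: float = 0.0):
    """Read a titration TSV with columns ``concentration`` (unit-suffixed
    strings or molar numbers) and either ``delta_p`` or ``population``
    (percent; baseline subtracted)."""
    from .binding import TitrationSeries
    from .units import parse_concentration

    df = read_table(path)
    if "concentration" not in df.columns:
        raise ValueError("titration table needs a 'concentration' column")
    conc = np.array([parse_concentration(v) for v in df["concentration"]])
    if "delta_p" in df.columns:
        dp = df["delta_p"].to_numpy(dtype=float)
    elif "population" in df.columns:
        dp = df["population"].to_numpy(dtype=float) - baseline
    else:
        raise ValueError("titration table needs 'delta_p' or 'population'")
    return TitrationSeries(
        c_partner=conc,
        delta_p=dp,
        c_diub=parse_concentration(c_diub),
        baseline_population=baseline,
    )
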