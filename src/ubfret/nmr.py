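"""Chemical-shift-perturbation and PRE interface mapping.

Binding shifts the amide resonances of interfacial residues.  The combined
¹H/¹⁵N chemical shift perturbation per residue is

    Δδ = sqrt(0.5 * (Δδ_H² + 0.2 * Δδ_N²))        [ppm]

with the 0.2 factor compressing the wider ¹⁵N scale.  Residues whose peaks
vanish on complex formation (intermediate exchange broadening) carry a
``disappeared`` flag and are always counted as interfacial.

A paramagnetic spin label enhances the transverse relaxation of nearby
(<~25 Å) amide protons.  With the standard two-time-point scheme, the PRE
rate is the para-minus-dia difference of single-exponential decay rates,

    Γ₂ = ln[(I_a^para · I_b^dia) / (I_b^para · I_a^dia)] / (t_b − t_a)

which is invariant to overall intensity scaling of either spectrum.
Residues broadened beyond detection in the paramagnetic sample have no
finite Γ₂ and are flagged.

Threshold conventions (both overridable): interface residues are those with
Δδ above mean + 1 SD of the table after trimming the largest 10% of values;
"very large" PREs default to Γ₂ > 20 s⁻¹.  Neither cutoff is a measured
quantity — they are stated conventions.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "csp_from_shifts",
    "compute_csp",
    "call_interface",
    "gamma2_from_two_points",
    "gamma2_single_delay",
    "flag_large_pre",
]


def csp_from_shifts(delta_h, delta_n):
    """Combined CSP Δδ = sqrt(0.5(Δδ_H² + 0.2·Δδ_N²)), ppm; vectorised."""
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    out = np.sqrt(0.5 * (dh ** 2 + 0.2 * dn ** 2))
    return float(out) if out.ndim == 0 else out


def _check_peaks(df: pd.DataFrame, label: str) -> pd.DataFrame:
    required = {"residue", "delta_h", "delta_n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{label} peak list missing columns {sorted(missing)}")
    if df["residue"].duplicated().any():
        dupes = df.loc[df["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"{label} peak list has duplicate residues: {dupes}")
    return df.set_index("residue")


def compute_csp(peaks_free: pd.DataFrame, peaks_bound: pd.DataFrame) -> pd.DataFrame:
    """Per-residue CSP table from free- and bound-state peak lists.

    Both inputs need columns ``residue``, ``delta_h``, ``delta_n`` (absolute
    chemical shifts, ppm).  Residues present free but absent bound are kept
    with the ``disappeared`` flag set (peak lost on complex formation);
    residues only present bound are reported via a warning rather than
    silently dropped.
    """
    free = _check_peaks(pd.DataFrame(peaks_free), "free")
    bound = _check_peaks(pd.DataFrame(peaks_bound), "bound")
    if free.index.intersection(bound.index).empty:
        raise ValueError("free and bound peak lists share no residues")
    bound_only = bound.index.difference(free.index)
    if len(bound_only):
        warnings.warn(
            f"{len(bound_only)} residues present only in the bound list: "
            f"{sorted(bound_only.tolist())}",
            stacklevel=2,
        )
    rows = []
    for res in free.index:
        if res in bound.index:
            dh = float(bound.loc[res, "delta_h"] - free.loc[res, "delta_h"])
            dn = float(bound.loc[res, "delta_n"] - free.loc[res, "delta_n"])
            rows.append(
                {
                    "residue": res,
                    "delta_h": dh,
                    "delta_n": dn,
                    "csp": csp_from_shifts(dh, dn),
                    "disappeared": False,
                }
            )
        else:
            rows.append(
                {"residue": res, "delta_h": np.nan, "delta_n": np.nan,
                 "csp": np.nan, "disappeared": True}
            )
    return pd.DataFrame(rows).sort_values("residue").reset_index(drop=True)


def csp_threshold(csp_values, trim_fraction: float = 0.1) -> float:
    """Mean + 1 SD of the CSPs after trimming the largest ``trim_fraction``
    of values, so a few strongly perturbed residues do not inflate their own
    cutoff."""
    vals = np.sort(np.asarray(csp_values, dtype=float))
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite CSP values")
    n_keep = max(1, int(math.ceil(vals.size * (1.0 - trim_fraction))))
    kept = vals[:n_keep]
    return float(kept.mean() + kept.std(ddof=0))


def call_interface(csp_table: pd.DataFrame, threshold: float | None = None) -> set[int]:
    """Residues with Δδ strictly above the threshold, plus all residues whose
    peaks disappeared.  ``threshold=None`` applies the trimmed mean + 1 SD
    convention."""
    df = pd.DataFrame(csp_table)
    if df.empty:
        raise ValueError("empty CSP table")
    if df["csp"].isna().all() and not df.get("disappeared", pd.Series(dtype=bool)).any():
        raise ValueError("CSP table is all-NaN")
    if threshold is None:
        threshold = csp_threshold(df["csp"].to_numpy())
    called = set(df.loc[df["csp"] > threshold, "residue"].astype(int))
    if "disappeared" in df.columns:
        called |= set(df.loc[df["disappeared"].astype(bool), "residue"].astype(int))
    return called


def gamma2_from_two_points(
    i_a_para: float,
    i_b_para: float,
    i_a_dia: float,
    i_b_dia: float,
    t_a: float,
    t_b: float,
) -> tuple[float, bool]:
    """PRE rate Γ₂ (s⁻¹) from peak intensities at two relaxation delays.

    Returns ``(gamma2, broadened)``; a vanishing paramagnetic intensity
    means the peak is broadened beyond detection (Γ₂ effectively infinite)
    and is reported as ``(inf, True)``.
    """
    if t_b <= t_a or t_a < 0:
        raise ValueError("need t_b > t_a >= 0")
    if i_a_dia <= 0 or i_b_dia <= 0:
        raise ValueError("diamagnetic intensities must be positive")
    if i_a_para < 0 or i_b_para < 0:
        raise ValueError("intensities must be nonnegative")
    if i_b_para == 0 or i_a_para == 0:
        return float("inf"), True
    gamma2 = math.log((i_a_para * i_b_dia) / (i_b_para * i_a_dia)) / (t_b - t_a)
    return gamma2, False


def gamma2_single_delay(i_para: float, i_dia: float, t: float) -> tuple[float, bool]:
    """Approximate single-delay PRE, Γ₂ ≈ −ln(I_para/I_dia)/t.

    Cruder than the two-point scheme (it folds differential losses during
    the transfer periods into Γ₂); provided as a labeled fallback for data
    with one delay only.
    """
    if t <= 0:
        raise ValueError("delay must be positive")
    if i_dia <= 0:
        raise ValueError("diamagnetic intensity must be positive")
    if i_para < 0:
        raise ValueError("intensities must be nonnegative")
    if i_para == 0:
        return float("inf"), True
    return -math.log(i_para / i_dia) / t, False


def flag_large_pre(pre_table: pd.DataFrame, gamma2_cutoff: float = 20.0) -> set[int]:
    """Residues with Γ₂ above the cutoff or broadened beyond detection.

    Expects columns ``residue`` and ``gamma2``; an optional boolean
    ``broadened`` column marks peaks with no finite Γ₂.
    """
    df = pd.DataFrame(pre_table)
    if df.empty:
        raise ValueError("empty PRE table")
    gamma2 = df["gamma2"].to_numpy(dtype=float)
    hot = df.loc[gamma2 > gamma2_cutoff, "residue"].astype(int)
    called = set(hot)
    if "broadened" in df.columns:
        called |= set(df.loc[df["broadened"].astype(bool), "residue"].astype(int))
    return called
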