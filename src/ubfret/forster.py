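"""Förster conversion between FRET efficiency and inter-dye distance.

The energy-transfer efficiency between a donor/acceptor pair separated by
distance r is

    E(r) = 1 / (1 + (r / R0)^6)

where R0 is the Förster distance of the pair (the distance at which
E = 0.5).  For the Alexa488/Cy5 pair used throughout this package the
default is R0 = 52 Å.

Because a flexible dye linker samples many positions, a structure model
yields an *ensemble* of inter-dye distances, one per conformer.  Two
averaging conventions exist in the literature and they differ whenever the
ensemble has spread (E is convex in r over most of its range):

* mean efficiency  ⟨E⟩ = mean over conformers of E(r_i)
* effective distance  r_eff = ⟨r^-6⟩^(-1/6), then E(r_eff)

:func:`ensemble_summary` reports both, plus the plain mean distance, so the
conventions can be compared explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ForsterContext",
    "DistanceEnsemble",
    "EnsembleSummary",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "ensemble_summary",
    "distances_from_models",
]


@dataclass(frozen=True)
class ForsterContext:
    """Förster distance context. ``r0`` in Å; E(r0) = 0.5 by definition."""

    r0: float = 52.0

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")


@dataclass
class DistanceEnsemble:
    """Per-conformer inter-dye distances in Å.

    ``source`` records provenance: ``"synthetic"`` for generated ensembles,
    ``"coordinates"`` for distances measured from atomic models.
    """

    distances: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.size == 0:
            raise ValueError("distance ensemble is empty")
        if np.any(self.distances <= 0):
            raise ValueError("all distances must be positive")

    def __len__(self) -> int:
        return int(self.distances.size)


@dataclass(frozen=True)
class EnsembleSummary:
    """All distance/efficiency averages for one ensemble (distances in Å)."""

    mean_r: float
    sd_r: float
    r_eff: float          # <r^-6>^(-1/6)
    mean_e: float         # <E(r)>
    sd_e: float
    e_of_mean_r: float    # E(<r>)
    e_of_r_eff: float     # E(r_eff)
    n: int


def efficiency_from_distance(r, ctx: ForsterContext = ForsterContext()):
    """FRET efficiency at inter-dye distance ``r`` (Å); scalar or array."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("distance must be positive")
    e = 1.0 / (1.0 + (r_arr / ctx.r0) ** 6)
    return float(e) if np.isscalar(r) or r_arr.ndim == 0 else e


def distance_from_efficiency(e, ctx: ForsterContext = ForsterContext()):
    """Inter-dye distance (Å) at FRET efficiency ``e``; exact inverse of
    :func:`efficiency_from_distance`.  Rejects e = 0 (infinite distance) and
    e = 1 (zero distance)."""
    e_arr = np.asarray(e, dtype=float)
    if np.any((e_arr <= 0) | (e_arr >= 1)):
        raise ValueError("efficiency must lie strictly between 0 and 1")
    r = ctx.r0 * ((1.0 - e_arr) / e_arr) ** (1.0 / 6.0)
    return float(r) if np.isscalar(e) or e_arr.ndim == 0 else r


def ensemble_summary(ens: DistanceEnsemble, ctx: ForsterContext = ForsterContext()) -> EnsembleSummary:
    """Summarise a distance ensemble under both averaging conventions."""
    r = ens.distances
    e = 1.0 / (1.0 + (r / ctx.r0) ** 6)
    r_eff = float(np.mean(r ** -6.0) ** (-1.0 / 6.0))
    mean_r = float(np.mean(r))
    return EnsembleSummary(
        mean_r=mean_r,
        sd_r=float(np.std(r, ddof=1)) if len(ens) > 1 else 0.0,
        r_eff=r_eff,
        mean_e=float(np.mean(e)),
        sd_e=float(np.std(e, ddof=1)) if len(ens) > 1 else 0.0,
        e_of_mean_r=efficiency_from_distance(mean_r, ctx),
        e_of_r_eff=efficiency_from_distance(r_eff, ctx),
        n=len(ens),
    )


def _parse_selection(selection: str) -> list[tuple[str, int, str]]:
    """Parse ``"chain:resnum:atomname"`` comma lists."""
    out = []
    for token in selection.split(","):
        parts = token.strip().split(":")
        if len(parts) != 3:
            raise ValueError(
                f"bad selector {token!r}; expected 'chain:resnum:atomname'"
            )
        chain, resnum, atom = parts
        out.append((chain.strip(), int(resnum), atom.strip()))
    if not out:
        raise ValueError("empty selection")
    return out


def _selection_center(model, selectors: list[tuple[str, int, str]]) -> np.ndarray:
    coords = []
    for chain_id, resnum, atom_name in selectors:
        for chain in model:
            if chain.id != chain_id:
                continue
            for residue in chain:
                if residue.id[1] != resnum:
                    continue
                for atom in residue:
                    if atom.get_name() == atom_name:
                        coords.append(atom.get_coord())
    if not coords:
        raise ValueError("selection matched no atoms")
    return np.mean(np.asarray(coords, dtype=float), axis=0)


def distances_from_models(
    pdb_path: str | Path,
    selection_a: str,
    selection_b: str,
) -> DistanceEnsemble:
    """Distance between the geometric centers of two atom selections, one
    value per MODEL of a (possibly multi-model) PDB file.

    Selections are comma lists of ``chain:resnum:atomname``; typical use is
    marking the dye-center pseudo-atoms or the aromatic ring atoms of each
    fluorophore.  A selection that matches nothing in some model raises,
    naming the model.
    """
    from Bio.PDB import PDBParser

    sel_a = _parse_selection(selection_a)
    sel_b = _parse_selection(selection_b)
    structure = PDBParser(QUIET=True).get_structure("models", str(pdb_path))
    distances = []
    for model in structure:
        try:
            ca = _selection_center(model, sel_a)
            cb = _selection_center(model, sel_b)
        except ValueError as err:
            raise ValueError(f"model {model.id}: {err}") from None
        distances.append(float(np.linalg.norm(ca - cb)))
    if not distances:
        raise ValueError("no MODEL records found")
    return DistanceEnsemble(np.asarray(distances), source="coordinates")
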