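"""Synthetic inputs for every pipeline stage.

The generators emulate, with the statistical structure the analysis
assumes, the raw measurements this package would otherwise need a confocal
microscope and an NMR spectrometer to produce:

* burst FRET efficiencies drawn from a weighted mixture of Gaussian
  conformational states, with either binomial shot noise (photon-count
  level) or Gaussian state broadening;
* binned photon time traces with bursts embedded in Poisson background,
  including a PIE acceptor-excitation channel and ground-truth burst
  locations for recall tests;
* titration series following the exact two-state binding isotherm with
  additive Gaussian noise and replicates;
* inter-dye distance ensembles with requested mean/SD (truncated at 0);
* per-residue CSP and PRE tables with a designated interface / hot set.

All draws come from one ``numpy.random.default_rng(seed)`` per call — no
global random state — so a fixed seed reproduces outputs exactly.

The three-state model of K48-diUb labeled at the 76C/0C sites (centers
0.74/0.57/0.23, populations 48/39/13%) is available as
:meth:`StateModel.diub_76c_0c`; the per-state width of 0.07 efficiency
units there is a modeling choice, not a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TitrationSeries, isotherm
from .bursts import PhotonTrace
from .forster import DistanceEnsemble
from .nmr import csp_from_shifts

__all__ = [
    "FretState",
    "StateModel",
    "SimConfig",
    "gen_burst_efficiencies",
    "gen_photon_trace",
    "gen_titration",
    "gen_distance_ensemble",
    "gen_nmr_tables",
]


@dataclass(frozen=True)
class FretState:
    """One conformational state: center efficiency, width (SD), weight."""

    center: float
    width: float
    weight: float


@dataclass
class StateModel:
    """Weighted mixture of Gaussian FRET states plus a donor-only fraction.

    ``donor_only_fraction`` models molecules without an active acceptor
    (bleached or unlabeled); experimentally these are removed by PIE
    filtering, so the generator emits them flagged, with near-zero apparent
    efficiency, and they never count toward the state weights.
    """

    states: list[FretState]
    donor_only_fraction: float = 0.1
    label: str = ""

    def __post_init__(self) -> None:
        self.states = [FretState(*s) if not isinstance(s, FretState) else s for s in self.states]
        if not self.states:
            raise ValueError("model needs at least one state")
        total = sum(s.weight for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state weights must sum to 1, got {total}")
        for s in self.states:
            if not 0.0 <= s.center <= 1.0:
                raise ValueError(f"state center {s.center} outside [0, 1]")
            if not s.width > 0:
                raise ValueError(f"state width must be positive, got {s.width}")
            if s.weight < 0:
                raise ValueError("state weights must be nonnegative")
        if not 0.0 <= self.donor_only_fraction < 1.0:
            raise ValueError("donor_only_fraction must be in [0, 1)")

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.states])

    @property
    def widths(self) -> np.ndarray:
        return np.array([s.width for s in self.states])

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.states])

    @classmethod
    def diub_76c_0c(cls, width: float = 0.07, donor_only_fraction: float = 0.0) -> "StateModel":
        """Three-state model of K48-diUb labeled at 76C (proximal) / 0C
        (distal): compact 0.74 (48%), semi-open 0.57 (39%), open 0.23 (13%)."""
        return cls(
            states=[
                FretState(0.74, width, 0.48),
                FretState(0.57, width, 0.39),
                FretState(0.23, width, 0.13),
            ],
            donor_only_fraction=donor_only_fraction,
            label="K48-diUb 76C/0C",
        )


@dataclass
class SimConfig:
    """Simulation knobs shared by the burst/trace generators.

    Brightness and background defaults are fabricated plumbing (no
    instrument parameters are being reproduced): 50 photons per burst and
    0.1 background counts/bin give clean threshold detection at the default
    gate of 4 counts/bin.
    """

    n_bursts: int = 5000
    photons_per_burst_mean: int = 50
    background_rate: float = 0.1
    burst_rate: float = 50.0
    bin_width: float = 0.001
    seed: int = 0
    noise_model: str = "binomial"

    def __post_init__(self) -> None:
        if self.n_bursts < 0:
            raise ValueError("n_bursts must be nonnegative")
        if self.photons_per_burst_mean < 1:
            raise ValueError("photons_per_burst_mean must be >= 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if self.noise_model not in ("gaussian", "binomial"):
            raise ValueError("noise_model must be 'gaussian' or 'binomial'")


def _draw_states(model: StateModel, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-burst state ids; donor-only bursts get id -1."""
    ids = rng.choice(len(model.states), size=n, p=model.weights)
    donor_only = rng.random(n) < model.donor_only_fraction
    ids = np.where(donor_only, -1, ids)
    return ids, donor_only


def _burst_sizes(mean: int, n: int, rng: np.random.Generator) -> np.ndarray:
    # shifted Poisson: at least one photon per burst
    return 1 + rng.poisson(max(mean - 1, 0), size=n)


def gen_burst_efficiencies(model: StateModel, cfg: SimConfig) -> pd.DataFrame:
    """Per-burst table (state_id, n_total, n_acceptor, efficiency, donor_only).

    Under ``binomial`` noise each burst's acceptor count is
    Binomial(n_total, center) — photon shot noise with SD sqrt(E(1−E)/N).
    Under ``gaussian`` noise the efficiency is drawn from the state's
    Gaussian directly, clipped to [0, 1], and widths set the spread.
    Donor-only bursts (state_id −1) have near-zero efficiency.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_bursts
    ids, donor_only = _draw_states(model, n, rng)
    n_total = _burst_sizes(cfg.photons_per_burst_mean, n, rng)

    centers = np.where(donor_only, 0.0, model.centers[np.maximum(ids, 0)])
    widths = model.widths[np.maximum(ids, 0)]
    if cfg.noise_model == "binomial":
        n_acc = rng.binomial(n_total, centers)
        eff = n_acc / n_total
    else:
        eff = np.clip(rng.normal(centers, widths), 0.0, 1.0)
        eff = np.where(donor_only, np.abs(rng.normal(0.0, 0.02, size=n)).clip(0, 1), eff)
        n_acc = np.round(eff * n_total).astype(np.int64)
    return pd.DataFrame(
        {
            "state_id": ids,
            "n_total": n_total,
            "n_acceptor": n_acc,
            "efficiency": eff,
            "donor_only": donor_only,
        }
    )


def gen_photon_trace(
    model: StateModel,
    cfg: SimConfig,
    aex_brightness: float = 0.3,
    n_bins: int | None = None,
) -> tuple[PhotonTrace, pd.DataFrame]:
    """Binned three-channel trace with bursts embedded in Poisson background.

    Bursts occupy 1–3 consecutive bins (uniform), never overlap, and their
    photons split donor/acceptor binomially at the state's center
    efficiency.  The PIE channel receives ~``aex_brightness``·n_total extra
    acceptor-excitation photons per burst — except for donor-only bursts,
    which have no active acceptor and get none.  Returns the trace and a
    ground-truth table (start_bin, end_bin, state_id, donor_only, n_photons)
    for detection-recall tests.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_bursts
    durations = rng.integers(1, 4, size=n) if n else np.empty(0, dtype=np.int64)
    if n_bins is None:
        bursts_per_bin = cfg.burst_rate * cfg.bin_width
        n_bins = int(np.ceil(max(n, 1) / max(bursts_per_bin, 1e-12)))
    if n_bins <= 0:
        raise ValueError("requested zero-length trace")
    occupied = int(durations.sum())
    free = n_bins - occupied
    if n and free < n + 1:
        n_bins = occupied + (n + 1) * 2
        free = n_bins - occupied

    donor = np.zeros(n_bins, dtype=np.int64)
    acceptor = np.zeros(n_bins, dtype=np.int64)
    aex = np.zeros(n_bins, dtype=np.int64)

    truth_rows = []
    if n:
        # distribute the free bins as n+1 random gaps => non-overlapping bursts
        gaps = rng.multinomial(free - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1
        ids, donor_only = _draw_states(model, n, rng)
        n_total = _burst_sizes(cfg.photons_per_burst_mean, n, rng)
        centers = np.where(donor_only, 0.0, model.centers[np.maximum(ids, 0)])
        pos = 0
        for i in range(n):
            pos += gaps[i]
            start, dur = pos, int(durations[i])
            per_bin = rng.multinomial(n_total[i], np.full(dur, 1.0 / dur))
            acc_per_bin = rng.binomial(per_bin, centers[i])
            donor[start : start + dur] += per_bin - acc_per_bin
            acceptor[start : start + dur] += acc_per_bin
            if not donor_only[i]:
                n_aex = rng.poisson(aex_brightness * n_total[i])
                aex[start : start + dur] += rng.multinomial(n_aex, np.full(dur, 1.0 / dur))
            truth_rows.append(
                {
                    "start_bin": start,
                    "end_bin": start + dur - 1,
                    "state_id": int(ids[i]),
                    "donor_only": bool(donor_only[i]),
                    "n_photons": int(n_total[i]),
                }
            )
            pos += dur

    if cfg.background_rate > 0:
        donor += rng.poisson(cfg.background_rate, size=n_bins)
        acceptor += rng.poisson(cfg.background_rate, size=n_bins)
        aex += rng.poisson(cfg.background_rate, size=n_bins)

    trace = PhotonTrace(
        bin_width=cfg.bin_width, donor=donor, acceptor=acceptor, aex_acceptor=aex
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["start_bin", "end_bin", "state_id", "donor_only", "n_photons"],
    )
    return trace, truth


def gen_titration(
    kd: float,
    p_max: float,
    baseline: float,
    c_diub: float,
    concentrations,
    noise_sd: float = 0.0,
    n_rep: int = 1,
    seed: int = 0,
) -> TitrationSeries:
    """Titration series: ΔP from the exact isotherm plus Gaussian noise,
    each concentration replicated ``n_rep`` times.  All concentrations in
    molar; populations in percent."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    c_rep = np.repeat(conc, n_rep)
    dp = isotherm(c_rep, c_diub, kd, p_max)
    if noise_sd > 0:
        dp = dp + rng.normal(0.0, noise_sd, size=c_rep.size)
    return TitrationSeries(
        c_partner=c_rep, delta_p=dp, c_diub=c_diub, baseline_population=baseline
    )


def gen_distance_ensemble(mean: float, sd: float, n: int, seed: int = 0) -> DistanceEnsemble:
    """``n`` inter-dye distances ~ Normal(mean, sd) (Å), truncated at > 0
    by resampling."""
    if not mean > 0:
        raise ValueError("mean distance must be positive")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if n < 1 or (n < 2 and sd > 0):
        raise ValueError("need n >= 2 when sd > 0")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return DistanceEnsemble(np.full(n, float(mean)))
    d = rng.normal(mean, sd, size=n)
    bad = d <= 0
    while bad.any():
        d[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = d <= 0
    return DistanceEnsemble(d)


def gen_nmr_tables(
    n_residues: int,
    interface: set[int],
    csp_effect: float = 0.2,
    pre_hot: set[int] = frozenset(),
    gamma2_hot: float = 80.0,
    gamma2_baseline: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
    pre_delay: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-residue CSP and PRE tables with a designated interface.

    Interface residues get Δδ_H = ``csp_effect`` ppm and Δδ_N = 2·csp_effect
    ppm; everything else is baseline noise.  ``pre_hot`` residues get
    Γ₂ = ``gamma2_hot`` (s⁻¹); pass ``inf`` to mark them broadened beyond
    detection (intensity ratio 0).  Intensity ratios follow
    exp(−Γ₂·pre_delay).  Residue numbering is 1-based.
    """
    if n_residues < 1:
        raise ValueError("empty residue range")
    residues = np.arange(1, n_residues + 1)
    bad = (set(interface) | set(pre_hot)) - set(residues.tolist())
    if bad:
        raise ValueError(f"residues outside 1..{n_residues}: {sorted(bad)}")
    rng = np.random.default_rng(seed)

    in_iface = np.isin(residues, list(interface))
    dh = np.where(in_iface, csp_effect, 0.0) + (rng.normal(0, noise, n_residues) if noise > 0 else 0.0)
    dn = np.where(in_iface, 2.0 * csp_effect, 0.0) + (rng.normal(0, 5 * noise, n_residues) if noise > 0 else 0.0)
    csp_table = pd.DataFrame(
        {
            "residue": residues,
            "delta_h": dh,
            "delta_n": dn,
            "csp": csp_from_shifts(dh, dn),
            "disappeared": False,
        }
    )

    hot = np.isin(residues, list(pre_hot))
    gamma2 = np.where(hot, gamma2_hot, gamma2_baseline).astype(float)
    if noise > 0:
        finite = np.isfinite(gamma2)
        gamma2[finite] = np.abs(gamma2[finite] + rng.normal(0, noise * 10, int(finite.sum())))
    with np.errstate(over="ignore"):
        ratio = np.exp(-gamma2 * pre_delay)
    broadened = ~np.isfinite(gamma2)
    ratio = np.where(broadened, 0.0, ratio)
    pre_table = pd.DataFrame(
        {
            "residue": residues,
            "i_para_over_i_dia": ratio,
            "gamma2": gamma2,
            "error": np.where(broadened, np.nan, 0.05 * np.maximum(gamma2, 1.0)),
            "broadened": broadened,
        }
    )
    return csp_table, pre_table
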