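"""Kinetic Monte Carlo of I-band titin elasticity under cyclic force.

The filament length is the summed freely-jointed-chain extension of the
unstructured contour (N2B and PEVK springs plus the released residues of
unfolded Ig domains) and a fixed axial contribution per folded Ig.  Each
10 ms step, every Ig domain attempts the transitions of its class with
probability 1 - exp(-k(F) dt): unfolding, refolding (only near the force
trough), and, for triad-containing domains, isomerization of the native
CysB-CysG disulfide.  Pair-class domains carry the matching single
disulfide and cannot isomerize; SINGLE/NONE domains are always
reduced-like.

The default kinetic parameters are the package's own calibration for the
low-force regime (see docs/methods.md): one unfolding Bell pair shared
by all Ig classes, the measured zero-force folding rates of the oxidized
states, a slow folding rate for reduced cysteine-containing domains, and
the faster folding of cysteine-free I-band domains.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from . import polymer_models as pm
from .states import Redox


class CysClass(enum.Enum):
    TRIAD = "triad"
    PAIR_BF = "pair_bf"
    PAIR_FG = "pair_fg"
    PAIR_BG = "pair_bg"
    SINGLE = "single"
    NONE = "none"


#: residues sequestered by the disulfide each class forms when oxidized
_OXIDIZED_REDOX = {
    CysClass.TRIAD: Redox.SS_BG,
    CysClass.PAIR_BG: Redox.SS_BG,
    CysClass.PAIR_BF: Redox.SS_BF,
    CysClass.PAIR_FG: Redox.SS_FG,
    CysClass.SINGLE: Redox.RED,
    CysClass.NONE: Redox.RED,
}


@dataclass(frozen=True)
class IsoformSpec:
    """I-band inventory of one titin isoform.

    Spring ranges are 1-based inclusive residue positions in the
    canonical sequence; the Ig inventory maps cysteine classes to domain
    counts.  N2BA defaults follow the canonical-sequence annotation
    (N2B spring 3712-4289, PEVK 10216-12022, 101 I-band Igs); the N2B
    isoform keeps the short PEVK (11851-12022) and a reduced inventory
    with ~9% triad-containing domains.
    """

    name: str
    n2b_range: tuple = (3712, 4289)
    pevk_range: tuple = (10216, 12022)
    ig_classes: dict = field(default_factory=dict)
    folded_ig_nm: float = 4.4
    geometry: pm.DomainGeometry = field(default_factory=pm.DomainGeometry)
    topology: pm.DisulfideTopology = field(default_factory=pm.DisulfideTopology)

    def __post_init__(self) -> None:
        for lo, hi in (self.n2b_range, self.pevk_range):
            if hi < lo:
                raise ValueError("spring ranges must satisfy start <= end")

    @property
    def spring_residues(self) -> int:
        return (self.n2b_range[1] - self.n2b_range[0] + 1) + \
               (self.pevk_range[1] - self.pevk_range[0] + 1)

    @property
    def n_igs(self) -> int:
        return sum(self.ig_classes.values())

    @classmethod
    def n2ba(cls) -> "IsoformSpec":
        return cls(name="N2BA", ig_classes={
            CysClass.TRIAD: 21, CysClass.PAIR_BF: 24, CysClass.PAIR_FG: 17,
            CysClass.PAIR_BG: 6, CysClass.SINGLE: 24, CysClass.NONE: 9,
        })

    @classmethod
    def n2b(cls) -> "IsoformSpec":
        # constructed default: 44 I-band Igs with a 9% triad fraction
        return cls(name="N2B", pevk_range=(11851, 12022), ig_classes={
            CysClass.TRIAD: 4, CysClass.PAIR_BF: 8, CysClass.PAIR_FG: 5,
            CysClass.PAIR_BG: 2, CysClass.SINGLE: 12, CysClass.NONE: 13,
        })


@dataclass(frozen=True)
class FilamentRates:
    """Per-class kinetics for the filament simulation.

    One unfolding Bell pair is shared by all Ig classes; folding rates
    are zero-force values applied only while F < `refold_force_max`.
    """

    k0_u: float = 2.8e-3
    dx_u: float = 0.3
    k_iso1: float = 0.021
    k_iso2: float = 0.027
    k_reiso: float = 0.005      # used only when reisomerization is enabled
    k_fold_ox: dict = field(default_factory=lambda: {
        Redox.SS_BG: 0.058, Redox.SS_BF: 0.054, Redox.SS_FG: 0.0})
    k_fold_red_cys: float = 0.01   # reduced cysteine-containing Igs
    k_fold_plain: float = 0.3      # cysteine-free / single-cysteine Igs
    refold_force_max: float = 1.0
    kT: float = pm.KT_ROOM


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.010            # s
    duration: float = 1200.0     # s (20 min)
    f_min: float = 0.0           # pN
    f_max: float = 30.0          # pN
    frequency: float = 1.0       # Hz
    redox_scenario: str = "all-oxidized"   # or "all-reduced"
    reisomerize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt > 0.010 + 1e-12:
            raise ValueError("dt must be <= 10 ms for dt-stable results")
        if self.redox_scenario not in ("all-oxidized", "all-reduced"):
            raise ValueError("redox_scenario must be all-oxidized/all-reduced")


def triangle_force(t, f_min: float, f_max: float, frequency: float):
    """Triangle wave rising from f_min at t=0 to f_max at half period."""
    phase = (np.asarray(t) * frequency) % 1.0
    tri = np.where(phase < 0.5, 2 * phase, 2 * (1 - phase))
    return f_min + (f_max - f_min) * tri


# internal integer codes for domain states
_FOLDED, _U_RED, _U_BG, _U_BF, _U_FG = 0, 1, 2, 3, 4
_REDOX_OF = {_U_RED: Redox.RED, _U_BG: Redox.SS_BG,
             _U_BF: Redox.SS_BF, _U_FG: Redox.SS_FG}


@dataclass
class FilamentTrajectory:
    time: np.ndarray
    force: np.ndarray
    length: np.ndarray
    cycle_peak_times: np.ndarray
    cycle_peak_lengths: np.ndarray
    state_counts: dict
    dt: float

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.time, "force_pN": self.force,
                             "length_nm": self.length})


def filament_length(
    n_folded: int,
    free_residues: float,
    F: float,
    isoform: IsoformSpec,
    params: pm.PolymerParams | None = None,
) -> float:
    """Length (nm) of the I-band at force F for a given composition.

    `free_residues` counts unstructured, non-sequestered residues from
    unfolded Ig domains; the two entropic springs are always included.
    """
    params = params or pm.PolymerParams()
    if F < 0:
        raise ValueError("force must be non-negative")
    z = pm.fjc_fractional_extension(F, params)
    contour = (isoform.spring_residues + free_residues) * params.l_aa
    return contour * z + n_folded * isoform.folded_ig_nm


def run_filament_mc(
    isoform: IsoformSpec,
    config: SimulationConfig,
    rates: FilamentRates | None = None,
    params: pm.PolymerParams | None = None,
    n_replicates: int = 1,
) -> FilamentTrajectory:
    """Fixed-step kinetic Monte Carlo of the whole I-band.

    All Igs start folded; under "all-oxidized" every possible disulfide
    is formed, under "all-reduced" all cysteines are free.  Per step each
    domain fires at most one transition, drawn from per-transition
    probabilities 1 - exp(-k dt) (the 10 ms step keeps max(k) dt << 1).

    `n_replicates` independent filaments are propagated in one vectorized
    pass and the reported length is their mean, which cuts the Monte
    Carlo variance of steady-state summaries at nearly no extra cost.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rates = rates or FilamentRates()
    params = params or pm.PolymerParams()
    geom = isoform.geometry
    topo = isoform.topology
    oxidized = config.redox_scenario == "all-oxidized"

    classes: list[CysClass] = []
    for cls_, count in isoform.ig_classes.items():
        classes.extend([cls_] * count)
    classes = classes * n_replicates
    n_dom = len(classes)
    cls_arr = np.array([c.value for c in classes], dtype=object)

    is_triad = np.array([c is CysClass.TRIAD for c in classes])

    # state code per domain: folded or unfolded with redox
    state = np.full(n_dom, _FOLDED, dtype=np.int8)
    # redox while folded (chemistry frozen): BG/BF/FG/RED per class
    folded_redox = np.array(
        [_OXIDIZED_REDOX[c] if (oxidized and _OXIDIZED_REDOX[c] is not Redox.RED)
         else Redox.RED for c in classes], dtype=object)

    n_ext = geom.n_ext

    n_steps = int(round(config.duration / config.dt))
    t = np.arange(n_steps + 1) * config.dt
    F = triangle_force(t, config.f_min, config.f_max, config.frequency)
    z_all = pm.fjc_fractional_extension(F, params)
    # midpoint force for transition rates: O(dt^2) discretization error
    F_mid = triangle_force(t[:-1] + 0.5 * config.dt, config.f_min,
                           config.f_max, config.frequency)
    # exact per-step time spent below the refolding threshold, so the
    # refold exposure per cycle does not depend on the sampling grid
    period = 1.0 / config.frequency
    slope = 2.0 * (config.f_max - config.f_min) / period
    if rates.refold_force_max > config.f_min and slope > 0:
        w = min((rates.refold_force_max - config.f_min) / slope, period / 2)
    else:
        w = 0.0
    s0 = t[:-1] % period
    s1 = s0 + config.dt
    # troughs sit at multiples of the period; windows [0, w) and (T-w, T]
    below = (np.clip(np.minimum(s1, w) - s0, 0.0, None)
             + np.clip(s1 - np.maximum(s0, period - w), 0.0, None))
    below = np.minimum(below, config.dt)

    # per-class fold rates for reduced/unfolded-red domains
    kfold_red = np.where(
        np.isin(cls_arr, [CysClass.SINGLE.value, CysClass.NONE.value]),
        rates.k_fold_plain, rates.k_fold_red_cys).astype(float)

    rng = np.random.default_rng(config.seed)
    lengths = np.empty(n_steps + 1)
    spring_res = isoform.spring_residues

    def redox_code(rx: Redox) -> int:
        return {Redox.RED: _U_RED, Redox.SS_BG: _U_BG,
                Redox.SS_BF: _U_BF, Redox.SS_FG: _U_FG}[rx]

    # free (non-sequestered) unfolded residues per state code
    free_by_code = np.array([0, n_ext, n_ext - topo.loop_BG,
                             n_ext - topo.loop_BF, n_ext - topo.loop_FG],
                            dtype=float)

    kf_bg = rates.k_fold_ox[Redox.SS_BG]
    kf_bf = rates.k_fold_ox[Redox.SS_BF]
    kf_fg = rates.k_fold_ox[Redox.SS_FG]
    dt = config.dt
    p_iso1 = 1.0 - math.exp(-rates.k_iso1 * dt)
    p_iso2 = 1.0 - math.exp(-rates.k_iso2 * dt)
    p_reiso = (1.0 - math.exp(-rates.k_reiso * dt)) if config.reisomerize else 0.0

    for i in range(n_steps + 1):
        lengths[i] = spring_res * params.l_aa * z_all[i] + (
            free_by_code[state].sum() * params.l_aa * z_all[i]
            + np.count_nonzero(state == _FOLDED) * isoform.folded_ig_nm
        ) / n_replicates
        if i == n_steps:
            break
        u = rng.random(n_dom)
        folded = state == _FOLDED
        # unfolding, at the midpoint force of the step
        k_u = rates.k0_u * math.exp(F_mid[i] * rates.dx_u / rates.kT)
        p_u = 1.0 - math.exp(-k_u * dt)
        unfold = folded & (u < p_u)
        # refolding, gated to the sub-threshold time within this step
        if below[i] > 0:
            kf = np.zeros(n_dom)
            kf[state == _U_RED] = kfold_red[state == _U_RED]
            kf[state == _U_BG] = kf_bg
            kf[state == _U_BF] = kf_bf
            kf[state == _U_FG] = kf_fg
            refold = (~folded) & (u < 1.0 - np.exp(-kf * below[i]))
        else:
            refold = np.zeros(n_dom, dtype=bool)
        # isomerization of unfolded B-G triads (second independent draw)
        u2 = rng.random(n_dom)
        can_iso = (state == _U_BG) & is_triad & ~refold
        iso1 = can_iso & (u2 < p_iso1)
        iso2 = can_iso & (u2 >= p_iso1) & (u2 < p_iso1 + p_iso2)
        if p_reiso > 0:
            can_back = np.isin(state, (_U_BF, _U_FG)) & is_triad & ~refold
            back = can_back & (u2 < p_reiso)
        else:
            back = np.zeros(n_dom, dtype=bool)

        # apply: unfold first (folded domains), then unfolded-domain moves
        new_state = state.copy()
        if unfold.any():
            codes = np.array([redox_code(rx) for rx in folded_redox[unfold]])
            new_state[unfold] = codes
        if refold.any():
            for j in np.nonzero(refold)[0]:
                folded_redox[j] = _REDOX_OF[int(state[j])]
            new_state[refold] = _FOLDED
        new_state[iso1] = _U_BF
        new_state[iso2] = _U_FG
        new_state[back] = _U_BG
        state = new_state

    # per-cycle peak-force summaries
    steps_per_cycle = int(round(1.0 / (config.frequency * dt)))
    peak_offset = steps_per_cycle // 2  # triangle peaks at half period
    peak_idx = np.arange(peak_offset, n_steps + 1, steps_per_cycle)

    return FilamentTrajectory(
        time=t, force=F, length=lengths,
        cycle_peak_times=t[peak_idx],
        cycle_peak_lengths=lengths[peak_idx],
        state_counts={
            "n_replicates": n_replicates,
            "final_folded": int(np.count_nonzero(state == _FOLDED)),
            "final_unfolded": int(np.count_nonzero(state != _FOLDED)),
            "final_unfolded_red": int(np.count_nonzero(state == _U_RED)),
            "final_unfolded_bg": int(np.count_nonzero(state == _U_BG)),
            "final_unfolded_bf": int(np.count_nonzero(state == _U_BF)),
            "final_unfolded_fg": int(np.count_nonzero(state == _U_FG)),
        },
        dt=dt,
    )


def residue_accounting(topology: pm.DisulfideTopology,
                       geometry: pm.DomainGeometry) -> dict:
    """Free + sequestered residue counts per domain state.

    In every state of a domain the free and sequestered unfolded residues
    sum to ``n_ext`` (folded domains hold all of them), which is the
    conservation law the trajectory relies on.
    """
    n_ext = geometry.n_ext
    table = {
        "folded": (0, 0, n_ext),
        "unfolded_red": (n_ext, 0, 0),
        "unfolded_bg": (n_ext - topology.loop_BG, topology.loop_BG, 0),
        "unfolded_bf": (n_ext - topology.loop_BF, topology.loop_BF, 0),
        "unfolded_fg": (n_ext - topology.loop_FG, topology.loop_FG, 0),
    }
    return {k: {"free": f, "sequestered": s, "folded": fd, "total": f + s + fd}
            for k, (f, s, fd) in table.items()}


@dataclass(frozen=True)
class SteadyStateSummary:
    mean_peak_length: float
    sd_peak_length: float
    slope_nm_per_s: float
    slope_p_value: float
    n_cycles: int


def steady_state_summary(traj: FilamentTrajectory, burn_in: float = 600.0,
                         window: float | None = None,
                         block_s: float = 100.0) -> SteadyStateSummary:
    """Mean/sd of the per-cycle peak-force length after burn-in, plus a
    linear-trend test over the summary window.

    Per-cycle peaks are strongly autocorrelated (the domain configuration
    relaxes over ~1/k_eff, tens of seconds), so the trend test regresses
    means of `block_s`-second blocks rather than raw cycles; otherwise
    any equilibrium excursion registers as a spuriously significant
    slope.
    """
    from scipy import stats

    t_end = traj.time[-1]
    if burn_in >= t_end:
        raise ValueError("burn_in must be shorter than the trajectory")
    lo = burn_in
    hi = t_end if window is None else min(t_end, burn_in + window)
    sel = (traj.cycle_peak_times >= lo) & (traj.cycle_peak_times <= hi)
    if not sel.any():
        raise ValueError("summary window contains no cycles")
    tt = traj.cycle_peak_times[sel]
    ll = traj.cycle_peak_lengths[sel]

    blocks = np.floor((tt - lo) / block_s).astype(int)
    b_t = np.array([tt[blocks == b].mean() for b in np.unique(blocks)])
    b_l = np.array([ll[blocks == b].mean() for b in np.unique(blocks)])
    if len(b_t) < 3 or np.allclose(b_l, b_l[0]):
        slope, p = 0.0, 1.0
    else:
        res = stats.linregress(b_t, b_l)
        slope, p = float(res.slope), float(res.pvalue)
    return SteadyStateSummary(
        mean_peak_length=float(ll.mean()), sd_peak_length=float(ll.std()),
        slope_nm_per_s=slope, slope_p_value=p, n_cycles=int(sel.sum()),
    )
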