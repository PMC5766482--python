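"""Synthetic force-clamp / ramp / three-pulse AFM recordings.

Traces are built from the ground truth of the stochastic domain engine:
the elastic baseline is the WLC extension of the currently released
contour at the instantaneous protocol force, each transition adds its
step smoothed by a finite instrument response, and Gaussian baseline
noise plus optional linear drift emulate the recording.  The ground
truth event log is returned alongside every trace so detector and
estimator performance can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import polymer_models as pm
from .domain_kinetics import (
    EventRecord,
    ForceProtocol,
    RateSet,
    simulate_ensemble,
)
from .states import DomainState, Fold, FOLDED_BG, FOLDED_RED
from .trace_analysis import Trace


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model of the synthetic instrument.

    sigma          Gaussian baseline noise per sample, nm
    drift          linear drift, nm/s
    sampling       sampling rate, Hz
    step_response  exponential smoothing time of instantaneous steps, ms
    """

    sigma: float = 1.0
    drift: float = 0.0
    sampling: float = 1000.0
    step_response: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.sampling <= 0:
            raise ValueError("sampling rate must be positive")
        if self.step_response < 0:
            raise ValueError("step response must be non-negative")


@dataclass(frozen=True)
class TetherSpec:
    """One tethered polyprotein: domain count, initial states, geometry."""

    n_domains: int = 8
    initial_state: DomainState = FOLDED_BG
    geometry: pm.DomainGeometry = field(default_factory=pm.DomainGeometry)
    topology: pm.DisulfideTopology = field(default_factory=pm.DisulfideTopology)

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("a tether needs at least one domain")

    @classmethod
    def i69_octamer_oxidized(cls) -> "TetherSpec":
        return cls(n_domains=8, initial_state=FOLDED_BG)

    @classmethod
    def i69_octamer_reduced(cls) -> "TetherSpec":
        return cls(n_domains=8, initial_state=FOLDED_RED)

    @classmethod
    def i65_i70_hexamer(cls, oxidized: bool = True) -> "TetherSpec":
        return cls(n_domains=6,
                   initial_state=FOLDED_BG if oxidized else FOLDED_RED)

    @classmethod
    def heteropolyprotein_i69(cls) -> "TetherSpec":
        """(I91dCys)2-I69-(I91dCys)2 modelled as its single triad domain;
        the cysteine-free fingerprint modules carry no redox chemistry."""
        return cls(n_domains=1, initial_state=FOLDED_BG)


def _validate(tether: TetherSpec, rates: RateSet) -> None:
    rx = tether.initial_state.redox
    if rx not in rates.k0_u or rx not in rates.k_fold:
        raise ValueError(f"RateSet is missing rates for redox state {rx}")


def synthesize_trace(
    tether: TetherSpec,
    rates: RateSet,
    protocol: ForceProtocol,
    noise: NoiseModel,
    seed: int,
    params: pm.PolymerParams | None = None,
) -> tuple[Trace, list[EventRecord]]:
    """Generate one noisy trace plus its ground-truth event log."""
    _validate(tether, rates)
    params = params or pm.PolymerParams()
    events, _ = simulate_ensemble(
        tether.n_domains, tether.initial_state, rates, protocol, seed,
        params=params, geom=tether.geometry, topo=tether.topology,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5AFE]))

    dt = 1.0 / noise.sampling
    n = int(np.floor(protocol.duration / dt)) + 1
    t = np.arange(n) * dt
    force = np.array([protocol.force(ti) for ti in t])
    z = np.zeros(n)
    pos = force > 0
    # piecewise-constant protocols repeat few force values; cache inversions
    cache: dict[float, float] = {}
    for i in np.nonzero(pos)[0]:
        f = float(force[i])
        if f not in cache:
            cache[f] = pm.wlc_fractional_extension(f, params)
        z[i] = cache[f]

    geom = tether.geometry
    topo = tether.topology
    # released contour (residues) and unfolded-domain count over time
    released = np.zeros(n)
    n_folded = np.full(n, float(tether.n_domains))
    tau = noise.step_response / 1000.0
    for e in events:
        from .polymer_models import released_residues

        dres = released_residues(e.before, e.after, topo, geom)
        dfold = (-1.0 if e.after.fold is Fold.UNFOLDED and e.before.fold is Fold.FOLDED
                 else (1.0 if e.before.fold is Fold.UNFOLDED and e.after.fold is Fold.FOLDED
                       else 0.0))
        after = t >= e.time
        if tau > 0:
            resp = np.zeros(n)
            resp[after] = 1.0 - np.exp(-(t[after] - e.time) / tau)
        else:
            resp = after.astype(float)
        released += dres * resp
        n_folded += dfold * resp

    extension = n_folded * geom.d_folded + released * params.l_aa * z
    extension += noise.drift * t
    if noise.sigma > 0:
        extension = extension + rng.normal(0.0, noise.sigma, size=n)

    trace = Trace(time=t, extension=extension, force=force,
                  metadata={"seed": seed, "n_domains": tether.n_domains,
                            "initial_state": str(tether.initial_state)})
    return trace, events


def synthesize_three_pulse(
    tether: TetherSpec,
    rates: RateSet,
    protocol: ForceProtocol,
    noise: NoiseModel,
    seed: int,
    params: pm.PolymerParams | None = None,
) -> tuple[Trace, list[EventRecord]]:
    """Three-pulse (unfold / quench / probe) synthesis.

    The protocol must have three segments with a zero-force quench so
    that refolding (gated at ``refold_force_max``) can occur; hidden
    chemistry during the quench (isomerization, reduction) is simulated
    by the same engine, and probe-pulse steps carry the redox-correct
    sizes.
    """
    if len(protocol.segments) != 3:
        raise ValueError("three-pulse protocol must have exactly 3 segments")
    quench = protocol.segments[1]
    if quench.F0 > rates.refold_force_max or quench.F1 > rates.refold_force_max:
        raise ValueError("quench force must not exceed refold_force_max")
    trace, events = synthesize_trace(tether, rates, protocol, noise, seed, params)
    u = protocol.segments[0].duration
    q = quench.duration
    p = protocol.segments[2].duration
    trace.metadata["pulse_windows"] = {"unfold": (0.0, u),
                                       "quench": (u, u + q),
                                       "probe": (u + q, u + q + p)}
    return trace, events


def synthesize_batch(
    n_traces: int,
    tether: TetherSpec,
    rates: RateSet,
    protocol: ForceProtocol,
    noise: NoiseModel,
    seed: int,
    params: pm.PolymerParams | None = None,
    three_pulse: bool = False,
):
    """Generate `n_traces` independent traces with per-trace derived seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_traces)
    make = synthesize_three_pulse if three_pulse else synthesize_trace
    out = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        trace, events = make(tether, rates, protocol, noise, child_seed, params)
        trace.metadata["trace_index"] = i
        out.append((trace, events))
    return out
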