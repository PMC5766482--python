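"""Analysis of staircase AFM traces.

Turns raw (time, extension, force) recordings into step calls via
least-squares change-point segmentation, fits sums of Gaussians to
step-size histograms, computes three-pulse refolding fractions with
bootstrap errors, and applies the polyprotein fingerprinting filters
used to select single-molecule traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit.models import GaussianModel


@dataclass
class Trace:
    """Uniformly sampled recording of one AFM experiment."""

    time: np.ndarray        # s
    extension: np.ndarray   # nm
    force: np.ndarray       # pN
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.extension) == len(self.force)):
            raise ValueError("time, extension and force must have equal length")
        if np.any(~np.isfinite(self.extension)):
            raise ValueError("trace contains missing values")

    @property
    def dt(self) -> float:
        d = np.diff(self.time)
        if len(d) and not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise ValueError("trace is not uniformly sampled")
        return float(d[0]) if len(d) else 0.0

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "extension_nm": self.extension,
                      "force_pN": self.force}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **metadata) -> "Trace":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep)
        return cls(df["time_s"].to_numpy(), df["extension_nm"].to_numpy(),
                   df["force_pN"].to_numpy(), metadata=metadata)


@dataclass(frozen=True)
class StepCall:
    time: float        # s
    size: float        # nm, post - pre
    pre_level: float   # nm
    post_level: float  # nm
    force: float       # pN


@dataclass(frozen=True)
class HistogramFit:
    means: tuple
    sds: tuple
    amplitudes: tuple
    bin_width: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"means_nm": list(self.means), "sds_nm": list(self.sds),
                       "amplitudes": list(self.amplitudes),
                       "bin_width_nm": self.bin_width}, fh, indent=2)


# ---------------------------------------------------------------------------
# change-point step detection

def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best single change point of a segment by least squares.

    Returns (index, gain) where gain is the drop in SSE when splitting
    before `index`.  O(n) using cumulative sums.
    """
    n = len(y)
    csum = np.cumsum(y)
    total = csum[-1]
    k = np.arange(1, n)
    left_mean = csum[:-1] / k
    right_mean = (total - csum[:-1]) / (n - k)
    # SSE reduction of a two-mean fit relative to one mean
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    i = int(np.argmax(gain))
    return i + 1, float(gain[i])


def _segment(y: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Binary segmentation: recursively split while SSE gain > penalty."""
    breaks: list[int] = []

    def rec(lo: int, hi: int) -> None:
        if hi - lo < 2 * min_size:
            return
        seg = y[lo:hi]
        # restrict admissible split points to respect min plateau length
        n = len(seg)
        csum = np.cumsum(seg)
        total = csum[-1]
        k = np.arange(1, n)
        valid = (k >= min_size) & (n - k >= min_size)
        if not valid.any():
            return
        left_mean = csum[:-1] / k
        right_mean = (total - csum[:-1]) / (n - k)
        gain = k * (n - k) / n * (left_mean - right_mean) ** 2
        gain[~valid] = -np.inf
        i = int(np.argmax(gain))
        if gain[i] <= penalty:
            return
        cut = lo + i + 1
        breaks.append(cut)
        rec(lo, cut)
        rec(cut, hi)

    rec(0, len(y))
    return sorted(breaks)


def _refit_break_clusters(y: np.ndarray, breaks: list[int],
                          gap: int) -> list[int]:
    """Collapse groups of breaks closer than `gap` into one change point.

    The min-plateau constraint can forbid the SSE-optimal split next to an
    instrument-response transient, leaving two breaks that straddle one
    step; each such cluster is replaced by the single best split between
    its neighbouring plateaus.
    """
    if not breaks:
        return breaks
    clusters: list[list[int]] = [[breaks[0]]]
    for b in breaks[1:]:
        if b - clusters[-1][-1] <= gap:
            clusters[-1].append(b)
        else:
            clusters.append([b])
    refit = []
    for i, cl in enumerate(clusters):
        if len(cl) == 1:
            refit.append(cl[0])
            continue
        lo = clusters[i - 1][-1] if i > 0 else 0
        hi = clusters[i + 1][0] if i + 1 < len(clusters) else len(y)
        idx, _ = _best_split(y[lo:hi])
        refit.append(lo + idx)
    return sorted(refit)


def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust noise estimate from first differences (MAD-based)."""
    d = np.diff(y)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


def detect_steps(trace: Trace, min_step: float = 2.0,
                 penalty: float | None = None,
                 min_plateau: int = 6) -> list[StepCall]:
    """Call extension steps by penalized least-squares segmentation.

    The penalty defaults to a BIC-style ``10 * sigma^2 * ln(n)`` with the
    noise sd estimated robustly from first differences.  Plateau levels
    are medians; calls smaller than `min_step` (nm) are merged away.
    The 6-sample minimum plateau resolves Poisson pile-up of unfolding
    events on multi-domain tethers at 1 kHz while producing no false
    calls on flat noise at the default penalty.
    """
    if len(trace.extension) < 100:
        raise ValueError("trace too short for step detection (<100 samples)")
    dt = trace.dt  # validates uniform sampling
    y = trace.extension
    sigma = max(estimate_noise_sd(y), 1e-6)
    if penalty is None:
        penalty = 10.0 * sigma ** 2 * np.log(len(y))

    breaks = _segment(y, penalty, min_plateau)

    # the instrument step response spreads a step over a few samples; a
    # guard zone after each break keeps the transient out of the level
    # estimates, and breaks closer than the guard are one event
    guard = min(min_plateau, max(1, int(round(0.005 / max(dt, 1e-9)))))
    breaks = _refit_break_clusters(y, breaks, min_plateau)

    def _levels(bks):
        edges = [0, *bks, len(y)]
        out = []
        for a, b in zip(edges[:-1], edges[1:]):
            skip = guard if (a > 0 and b - a > guard + 2) else 0
            out.append(float(np.median(y[a + skip:b])))
        return out

    # merge neighbouring plateaus whose level difference is below min_step
    while True:
        levels = _levels(breaks)
        diffs = np.abs(np.diff(levels))
        if len(diffs) == 0 or diffs.min() >= min_step:
            break
        j = int(np.argmin(diffs))
        breaks.pop(j)

    levels = _levels(breaks)
    calls = []
    for j, cut in enumerate(breaks):
        calls.append(StepCall(
            time=float(trace.time[cut]),
            size=levels[j + 1] - levels[j],
            pre_level=levels[j], post_level=levels[j + 1],
            force=float(trace.force[cut]),
        ))
    return calls


# ---------------------------------------------------------------------------
# histogram fitting

def fit_gaussian_mixture_hist(sizes, n_components: int = 1,
                              bin_width: float = 1.0) -> HistogramFit:
    """Least-squares fit of a sum of Gaussians to a binned histogram.

    Initial means are seeded from local maxima of the histogram; returns
    per-component mean, sd and amplitude.
    """
    sizes = np.asarray(sizes, dtype=float)
    if len(sizes) == 0:
        raise ValueError("no step sizes provided")
    if len(sizes) < 20 or len(sizes) < 10 * n_components:
        raise ValueError(
            f"need >= max(20, 10*n_components) sizes, got {len(sizes)}")
    lo = np.floor(sizes.min()) - 2 * bin_width
    hi = np.ceil(sizes.max()) + 2 * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(sizes, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # candidate peaks: local maxima by count
    order = np.argsort(counts)[::-1]
    peaks: list[float] = []
    for i in order:
        if counts[i] == 0:
            break
        if all(abs(centers[i] - pk) > 3 * bin_width for pk in peaks):
            peaks.append(float(centers[i]))
        if len(peaks) == n_components:
            break
    while len(peaks) < n_components:
        peaks.append(float(np.percentile(sizes, 100 * (len(peaks) + 0.5) / n_components)))

    model = None
    params = None
    for c, mu0 in enumerate(sorted(peaks)):
        g = GaussianModel(prefix=f"g{c}_")
        pars = g.make_params(center=mu0, sigma=max(bin_width, sizes.std() / n_components),
                             amplitude=counts.max() * bin_width * 2)
        pars[f"g{c}_sigma"].set(min=bin_width / 10)
        pars[f"g{c}_amplitude"].set(min=0)
        model = g if model is None else model + g
        params = pars if params is None else params.update(pars) or params
    result = model.fit(counts, params, x=centers)

    comps = sorted(range(n_components),
                   key=lambda c: result.params[f"g{c}_center"].value)
    return HistogramFit(
        means=tuple(result.params[f"g{c}_center"].value for c in comps),
        sds=tuple(result.params[f"g{c}_sigma"].value for c in comps),
        amplitudes=tuple(result.params[f"g{c}_amplitude"].value for c in comps),
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# refolding fraction

def refolding_fraction(n_unfold_first, n_unfold_probe, n_boot: int = 1000,
                       seed: int = 0) -> tuple[float, float]:
    """Three-pulse refolding fraction with bootstrap SEM.

    fraction = (total probe-pulse unfolding events) / (total unfold-pulse
    events); the SEM is the sd of the fraction over trace-level bootstrap
    resamples.
    """
    first = np.asarray(n_unfold_first, dtype=float)
    probe = np.asarray(n_unfold_probe, dtype=float)
    if first.sum() <= 0:
        raise ValueError("no unfolding events in the unfold pulse")
    frac = probe.sum() / first.sum()
    rng = np.random.default_rng(seed)
    n = len(first)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        denom = first[idx].sum()
        boots[b] = probe[idx].sum() / denom if denom > 0 else np.nan
    sem = float(np.nanstd(boots))
    return float(frac), sem


# ---------------------------------------------------------------------------
# trace selection (fingerprinting)

def fingerprint_filter(traces_with_steps, mode: str,
                       repeat_tolerance: float = 1.0,
                       extension_tolerance: float = 3.0):
    """Select traces by the single-molecule fingerprint criteria.

    mode "repeat-step": keep traces with at least two steps whose sizes
    agree within `repeat_tolerance` nm.

    mode "match-extension": keep three-pulse traces whose final
    unfold-pulse extension matches the final probe-pulse extension
    (before any isomerization step in the probe) within
    `extension_tolerance` nm; items must be (trace, steps) pairs where
    the trace carries `pulse_windows` metadata
    {"unfold": (t0, t1), "probe": (t0, t1)}.
    """
    if mode == "repeat-step":
        kept = []
        for trace, steps in traces_with_steps:
            sizes = np.array([s.size for s in steps])
            if len(sizes) >= 2:
                diffs = np.abs(sizes[:, None] - sizes[None, :])
                np.fill_diagonal(diffs, np.inf)
                if diffs.min() <= repeat_tolerance:
                    kept.append((trace, steps))
        return kept
    if mode == "match-extension":
        kept = []
        for trace, steps in traces_with_steps:
            win = trace.metadata.get("pulse_windows")
            if win is None:
                raise ValueError("match-extension mode needs pulse_windows metadata")
            u0, u1 = win["unfold"]
            p0, p1 = win["probe"]
            t = trace.time
            ext_unfold_end = float(np.median(trace.extension[(t >= u1 - 0.05) & (t <= u1)]))
            probe_steps = [s for s in steps if p0 <= s.time <= p1]
            iso = [s for s in probe_steps if trace.metadata.get(
                "iso_times") and any(abs(s.time - ti) < 0.05 for ti in trace.metadata["iso_times"])]
            t_cut = min((s.time for s in iso), default=p1)
            sel = (t >= t_cut - 0.05) & (t <= t_cut)
            if not sel.any():
                continue
            ext_probe_end = float(np.median(trace.extension[sel]))
            if abs(ext_probe_end - ext_unfold_end) <= extension_tolerance:
                kept.append((trace, steps))
        return kept
    raise ValueError(f"unknown fingerprint mode {mode!r}")


def steps_to_dataframe(calls: list[StepCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "time_s": [c.time for c in calls],
        "step_nm": [c.size for c in calls],
        "pre_nm": [c.pre_level for c in calls],
        "post_nm": [c.post_level for c in calls],
        "force_pN": [c.force for c in calls],
    })
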