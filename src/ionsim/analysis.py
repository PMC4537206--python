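"""Trace classification, bifurcation sweeps, and derived quantities.

Seizure (SZ), spreading-depression (SD), and anoxic-depolarization (AD)
events are operationalized from the membrane-potential trace:

* spike: upward crossing of ``spike_threshold`` with a refractory time;
* seizure: a cluster of >= ``sz_min_spikes`` spikes with inter-spike
  interval < ``sz_max_isi``, terminated by a spike-free gap or SD onset;
* SD: V above ``sd_v_threshold`` sustained longer than
  ``sd_min_duration`` with a low spike rate, recovering below
  ``sd_recovery_v`` without any parameter change;
* AD: an SD-like plateau that starts during an energy-deprivation
  interval;
* depolarized-locked: a plateau persisting to the end of the trace.

All thresholds are configuration-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import osmotic_target_volume
from .engine import Protocol, Trace, integrate, nominal_state
from .geometry import geometry_from_radius, radius_from_volume
from .parameters import ModelParameters, VariantFlags


@dataclass(frozen=True)
class ClassificationRules:
    spike_threshold: float = -20.0   # mV
    refractory: float = 0.002        # s
    sz_min_spikes: int = 5
    sz_max_isi: float = 0.5          # s
    sz_end_gap: float = 2.0          # s
    sd_v_threshold: float = -40.0    # mV; SD plateau level
    sd_min_duration: float = 5.0     # s
    sd_max_spike_rate: float = 2.0   # spikes/s inside a plateau
    sd_recovery_v: float = -50.0     # mV
    osc_threshold: float = 0.1       # mM, [K]o amplitude for "oscillating"
    recovery_window: float = 100.0   # s after O2 restoration
    recovery_dv: float = 5.0         # mV tolerance to pre-ED baseline


@dataclass
class Event:
    kind: str          # 'SZ' | 'SD' | 'AD'
    t_on: float
    t_off: float
    n_spikes: int = 0
    peak_K_o: float = float("nan")
    peak_pct_dvol: float = float("nan")
    recovered: bool = True


@dataclass
class TraceClassification:
    label: str                       # resting | SZ | SD-mixed | depolarized-locked
    events: list = field(default_factory=list)
    recovered_after_ed: bool | None = None

    @property
    def seizures(self):
        return [e for e in self.events if e.kind == "SZ"]

    @property
    def sd_events(self):
        return [e for e in self.events if e.kind in ("SD", "AD")]


def detect_spikes(t: np.ndarray, v: np.ndarray,
                  rules: ClassificationRules = ClassificationRules()
                  ) -> np.ndarray:
    """Spike times: upward threshold crossings with a refractory time."""
    up = np.flatnonzero((v[1:] > rules.spike_threshold)
                        & (v[:-1] <= rules.spike_threshold))
    if len(up) == 0:
        return np.empty(0)
    times = t[up + 1]
    keep = [times[0]]
    for s in times[1:]:
        if s - keep[-1] >= rules.refractory:
            keep.append(s)
    return np.asarray(keep)


def _plateau_segments(t, v, rules):
    """Contiguous runs whose 1-s rolling median V exceeds the SD
    threshold, longer than the minimum duration; short dips (< 1 s) are
    bridged.  The median filter removes spikes, so a fast-spiking
    seizure (inter-spike baseline far below threshold) is not mistaken
    for a depolarized plateau."""
    from scipy.ndimage import median_filter
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1e-3
    dec = max(1, int(round(0.01 / dt)))          # ~10-ms decimation
    vd = v[::dec]
    td = t[::dec]
    win = max(3, int(round(1.0 / (dt * dec))) | 1)   # ~1 s, odd
    vmed = median_filter(vd, size=win, mode="nearest")
    above_d = vmed > rules.sd_v_threshold
    # map back to the full-resolution index grid
    above = np.repeat(above_d, dec)[:len(v)]
    if len(above) < len(v):
        above = np.concatenate([above,
                                np.full(len(v) - len(above), above_d[-1])])
    if not above.any():
        return []
    idx = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(idx[~above[idx]] + 1)
    ends = list(idx[above[idx]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    segs = list(zip(starts, ends))
    merged = [segs[0]]
    for a, b in segs[1:]:
        pa, pb = merged[-1]
        if t[a] - t[pb - 1] < 1.0:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return [(a, b) for a, b in merged
            if t[b - 1] - t[a] >= rules.sd_min_duration]


def classify_trace(trace: Trace,
                   rules: ClassificationRules = ClassificationRules(),
                   transient: float | None = None) -> TraceClassification:
    """Detect seizures and SD/AD events and label the overall behavior."""
    if transient is None:
        transient = trace.meta.get("config", {}).get(
            "protocol", {}).get("transient_discard", 0.0)
    tr = trace.after(transient)
    t = tr.t
    if len(t) < 2:
        raise ValueError("trace too short after transient discard")
    v = tr["V"]
    ko = tr["K_o"]
    pct = tr["percent_dVol"]
    ed = trace.meta.get("ed_interval")
    spikes = detect_spikes(t, v, rules)

    events: list[Event] = []
    locked = False
    sd_segments = []
    for a, b in _plateau_segments(t, v, rules):
        t_on, t_off = t[a], t[b - 1]
        n_sp = int(np.sum((spikes >= t_on) & (spikes <= t_off)))
        if n_sp / max(t_off - t_on, 1e-9) > rules.sd_max_spike_rate:
            # the median filter can bridge the tail of a seizure into the
            # plateau: trim the leading spiking portion and re-test
            inside = spikes[(spikes >= t_on) & (spikes <= t_off)]
            t_trim = inside[-1] + 0.2
            a2 = a + int(np.searchsorted(t[a:b], t_trim))
            if a2 >= b or t[b - 1] - t[a2] < rules.sd_min_duration:
                continue  # a spiking episode, not a depolarized plateau
            a, t_on = a2, t[a2]
            n_sp = 0
        sd_segments.append((a, b))
        kind = "SD"
        if ed is not None and ed[0] <= t_on <= ed[1]:
            kind = "AD"
        after = v[b:]
        rec = bool(len(after) and (after.min() < rules.sd_recovery_v))
        if b >= len(v) - 1 or not rec:
            locked = t_off >= t[-1] - rules.sd_min_duration
        events.append(Event(kind, t_on, t_off, n_sp,
                            float(ko[a:b].max()),
                            float(np.nanmax(pct[a:b])), rec))

    # seizures: spike clusters outside accepted plateaus
    sd_spans = [(e.t_on, e.t_off) for e in events]

    def inside_sd(s):
        return any(a <= s <= b for a, b in sd_spans)

    free = np.array([s for s in spikes if not inside_sd(s)])
    i = 0
    while i < len(free):
        j = i
        while (j + 1 < len(free)
               and free[j + 1] - free[j] < max(rules.sz_max_isi,
                                               rules.sz_end_gap)):
            j += 1
        cluster = free[i:j + 1]
        isi_ok = (len(cluster) >= rules.sz_min_spikes
                  and np.median(np.diff(cluster)) < rules.sz_max_isi)
        if isi_ok:
            m = (t >= cluster[0]) & (t <= cluster[-1])
            events.append(Event("SZ", float(cluster[0]), float(cluster[-1]),
                                len(cluster),
                                float(ko[m].max()) if m.any() else np.nan,
                                float(np.nanmax(pct[m])) if m.any() else np.nan))
        i = j + 1
    events.sort(key=lambda e: e.t_on)

    recovered_after_ed = None
    if ed is not None:
        base_mask = t < ed[0]
        after_mask = (t >= ed[1]) & (t <= ed[1] + rules.recovery_window)
        if base_mask.any() and after_mask.any():
            v_base = float(np.median(v[base_mask][:max(1, base_mask.sum() // 2)]))
            recovered_after_ed = bool(
                np.min(np.abs(v[after_mask] - v_base)) < rules.recovery_dv)

    has_sd = any(e.kind in ("SD", "AD") for e in events)
    has_sz = any(e.kind == "SZ" for e in events)
    if locked:
        label = "depolarized-locked"
    elif has_sd:
        label = "SD-mixed"
    elif has_sz:
        label = "SZ"
    elif ko.max() - ko.min() > rules.osc_threshold:
        label = "SZ"   # subthreshold-spike [K]o oscillation counts as active
    else:
        label = "resting"
    return TraceClassification(label, events, recovered_after_ed)


def count_seizures_before_sd(trace: Trace,
                             rules: ClassificationRules = ClassificationRules(),
                             transient: float = 0.0):
    """Number of completed seizures strictly before the first SD onset.

    Returns ``(count, has_sd)``; count is 0 with ``has_sd=False`` when no
    SD occurs.
    """
    cl = classify_trace(trace, rules, transient)
    sds = cl.sd_events
    if not sds:
        return 0, False
    first_sd = min(e.t_on for e in sds)
    return sum(1 for e in cl.seizures if e.t_off < first_sd), True


# ---------------------------------------------------------------------------
# sweeps

@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep specification.

    ``parameter`` is one of r_in, beta, B_glia, tau_v, K_o_inf, O2_inf.
    """

    parameter: str
    values: tuple
    duration: float = 250.0
    transient: float = 150.0
    dt: float = 0.02
    observables: tuple = ("K_o",)

    _RECOGNIZED = ("r_in", "beta", "B_glia", "tau_v", "K_o_inf", "O2_inf")

    def __post_init__(self):
        if self.parameter not in self._RECOGNIZED:
            raise ValueError(f"{self.parameter!r} is not a recognized "
                             f"bifurcation parameter {self._RECOGNIZED}")
        v = np.asarray(self.values, dtype=float)
        if len(v) > 1 and not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
            raise ValueError("sweep grid must be strictly monotone")


@dataclass
class DiagramPoint:
    value: float
    label: str
    observable_max: dict
    observable_min: dict
    steady_state: float | None = None
    error: str | None = None


def _point_run(spec: SweepSpec, value: float, params: ModelParameters,
               flags: VariantFlags, base_r_in: float) -> Trace:
    p = params
    r_in = base_r_in
    if spec.parameter == "r_in":
        r_in = value
    elif spec.parameter == "beta":
        pass   # handled through a direct override below
    else:
        p = params.replace(**{spec.parameter: value})
    geo = geometry_from_radius(r_in)
    proto = Protocol(duration=spec.duration, dt=spec.dt,
                     transient_discard=spec.transient)
    if spec.parameter == "beta":
        proto = Protocol(duration=spec.duration, dt=spec.dt,
                         transient_discard=spec.transient,
                         schedule=((0.0, spec.duration, "beta", value),))
    need_derived = any(o not in ("K_o", "V", "Na_i", "Cl_i", "O2", "Vol")
                       for o in spec.observables)
    return integrate(nominal_state(geo, p), proto, p, flags, geo,
                     derived=need_derived)


def sweep_diagram(spec: SweepSpec, params: ModelParameters,
                  flags: VariantFlags, base_r_in: float = 4.82,
                  rules: ClassificationRules = ClassificationRules()
                  ) -> list:
    """Extrema-based one-parameter bifurcation diagram.

    Each grid point is an independent run from the nominal resting state;
    the transient is discarded and post-transient extrema of the
    observables recorded together with the behavioral label.  Per-point
    failures are recorded and the sweep continues.
    """
    points = []
    for value in spec.values:
        try:
            tr = _point_run(spec, float(value), params, flags, base_r_in)
            cl = classify_trace(tr, rules, spec.transient)
            tail = tr.after(spec.transient)
            omax = {o: float(tail[o].max()) for o in spec.observables}
            omin = {o: float(tail[o].min()) for o in spec.observables}
            ko_amp = tail["K_o"].max() - tail["K_o"].min()
            steady = float(tail["V"][-1]) if ko_amp <= rules.osc_threshold \
                else None
            points.append(DiagramPoint(float(value), cl.label, omax, omin,
                                       steady))
        except Exception as exc:   # per-point failure, sweep continues
            points.append(DiagramPoint(float(value), "error", {}, {},
                                       None, repr(exc)))
    return points


def two_parameter_map(spec1: SweepSpec, spec2: SweepSpec,
                      params: ModelParameters, flags: VariantFlags,
                      rules: ClassificationRules = ClassificationRules()):
    """Classification grid over two parameters plus region boundaries.

    Returns ``(grid, boundaries)``: ``grid[i][j]`` is the DiagramPoint at
    (spec1.values[i], spec2.values[j]); boundaries are polylines (in
    parameter coordinates) separating differently classified regions,
    extracted by marching squares on each region's indicator.
    """
    grid = []
    for v2 in spec2.values:
        if spec2.parameter == "r_in":
            pts = sweep_diagram(spec1, params, flags, base_r_in=float(v2),
                                rules=rules)
        else:
            p2 = params.replace(**{spec2.parameter: float(v2)})
            pts = sweep_diagram(spec1, p2, flags, rules=rules)
        grid.append(pts)
    grid = [list(col) for col in zip(*grid)]   # index as [i][j]

    labels = sorted({pt.label for row in grid for pt in row})
    lab_arr = np.array([[pt.label for pt in row] for row in grid])
    boundaries = {}
    try:
        from skimage import measure
        x = np.asarray(spec1.values, float)
        y = np.asarray(spec2.values, float)
        for lab in labels:
            mask = (lab_arr == lab).astype(float)
            for k, contour in enumerate(measure.find_contours(mask, 0.5)):
                xi = np.interp(contour[:, 0], np.arange(len(x)), x)
                yi = np.interp(contour[:, 1], np.arange(len(y)), y)
                boundaries.setdefault(lab, []).append(
                    np.column_stack([xi, yi]))
    except ImportError:  # boundary extraction is optional
        pass
    return grid, boundaries


# ---------------------------------------------------------------------------
# volume-derived quantities

def percent_volume_change(r_ins, r_ss):
    """Percent volume change implied by instantaneous vs reference
    radius: ((r_ins^3 - r_ss^3)/r_ss^3) * 100."""
    r_ins = np.asarray(r_ins, dtype=float)
    if np.any(np.asarray(r_ss) <= 0):
        raise ValueError("reference radius must be positive")
    return (r_ins**3 - np.asarray(r_ss)**3) / np.asarray(r_ss)**3 * 100.0


def swelling_overlay(trace: Trace, params: ModelParameters) -> np.ndarray:
    """Instantaneous radius implied by osmolarity along a fixed-volume
    trace: the osmotic target volume evaluated pointwise from the
    concentrations, converted to a radius (um)."""
    p = params
    pi_i = trace["Na_i"] + trace["Cl_i"] + trace["K_i"] + p.A_i + p.Ca_i
    pi_o = trace["Na_o"] + trace["Cl_o"] + trace["K_o"] + p.A_o + p.Ca_o
    vol0 = trace["Vol"]  # fixed-volume run: Vol is the reference volume
    vol_hat = osmotic_target_volume(pi_i, pi_o, vol0)
    return radius_from_volume(vol_hat)
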