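"""Pulsatile apical-area dynamics: trace normalization, T0 alignment,
aggregation, sine-amplitude estimation, and the mitotic-constriction
tests.

Live-imaged apical areas oscillate; mitotic cells superimpose on this a
high-amplitude constriction that reaches its minimum at anaphase. Traces
are normalized to each cell's own mean area (removing inter-cell size
variability), aligned to T0 — the anaphase frame for mitotic cells, the
minimum-area frame for non-mitotic cells — and summarized per timepoint
as mean +/- SEM. The pulse amplitude of each cell is the amplitude of a
sine curve fitted to its normalized trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .stats import StatResult, t_test


@dataclass
class CellTrace:
    """One cell's apical-area time series (minutes, um^2).

    ``anaphase_t`` is required for mitotic traces and must coincide with a
    sample time. ``lineage`` optionally marks a post-division daughter
    series (``mother_id`` plus ``retain`` flag); when two daughters of the
    same mother are present, only one is kept at alignment.
    """

    cell_id: str
    t: np.ndarray
    area: np.ndarray
    is_mitotic: bool = False
    anaphase_t: float | None = None
    lineage: dict | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.area.shape:
            raise ValueError(f"trace {self.cell_id}: t and area must be "
                             "1-D and equal length")
        if len(self.t) < 2:
            raise ValueError(f"trace {self.cell_id}: needs >= 2 samples")
        dt = np.diff(self.t)
        if (dt <= 0).any():
            raise ValueError(f"trace {self.cell_id}: times must be strictly "
                             "increasing")
        if not np.allclose(dt, dt[0]):
            raise ValueError(f"trace {self.cell_id}: non-uniform sampling")
        if self.is_mitotic:
            if self.anaphase_t is None:
                raise ValueError(f"mitotic trace {self.cell_id} lacks an "
                                 "anaphase annotation")
            if not np.isclose(self.t, self.anaphase_t).any():
                raise ValueError(f"trace {self.cell_id}: anaphase time does "
                                 "not coincide with a sample time")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class AlignedTraceSet:
    """Long-format aligned traces: cell_id, rel_t_min, norm_area, group."""

    data: pd.DataFrame
    dt: float
    n_daughters_dropped: int = 0


@dataclass
class SineFit:
    amplitude: float  # fraction of mean area, >= 0
    period: float  # min
    phase: float  # rad
    offset: float
    r2: float
    converged: bool

    def to_dict(self) -> dict:
        return {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                for k, v in vars(self).items()}


def normalize_trace(trace: CellTrace) -> np.ndarray:
    """Divide each sample by the cell's mean area; output mean is 1."""
    if (trace.area <= 0).any():
        raise ValueError(f"trace {trace.cell_id}: non-positive area")
    return trace.area / trace.area.mean()


def align_traces(traces: list[CellTrace]) -> AlignedTraceSet:
    """Align normalized traces to T0 (anaphase frame for mitotic cells;
    earliest minimum-area frame for non-mitotic cells).

    For divided cells annotated with lineage, exactly one daughter per
    mother is retained: the one flagged ``retain``, else the first by
    cell_id (deterministic); the count of dropped siblings is reported.
    """
    if not traces:
        raise ValueError("no traces to align")
    dts = {t.dt for t in traces}
    if len(dts) > 1:
        raise ValueError("traces have mixed frame intervals")
    dt = dts.pop()

    kept: list[CellTrace] = []
    dropped = 0
    by_mother: dict[str, list[CellTrace]] = {}
    for tr in traces:
        if tr.lineage and tr.lineage.get("mother_id"):
            by_mother.setdefault(tr.lineage["mother_id"], []).append(tr)
        else:
            kept.append(tr)
    for siblings in by_mother.values():
        flagged = [s for s in siblings if s.lineage.get("retain")]
        pool = flagged or sorted(siblings, key=lambda s: s.cell_id)
        kept.append(pool[0])
        dropped += len(siblings) - 1

    rows = []
    for tr in kept:
        norm = normalize_trace(tr)
        if tr.is_mitotic:
            t0 = tr.anaphase_t
        else:
            t0 = tr.t[int(np.argmin(tr.area))]  # argmin takes earliest tie
        rel = np.round((tr.t - t0) / dt).astype(int) * dt
        group = "mitotic" if tr.is_mitotic else "non-mitotic"
        rows.append(pd.DataFrame({"cell_id": tr.cell_id, "rel_t_min": rel,
                                  "norm_area": norm, "group": group}))
    return AlignedTraceSet(pd.concat(rows, ignore_index=True), dt=dt,
                           n_daughters_dropped=dropped)


def aggregate_aligned(aligned: AlignedTraceSet) -> pd.DataFrame:
    """Per relative timepoint and group: n, mean, SEM (= sd/sqrt(n));
    SEM is NaN where only one cell contributes."""
    def _sem(x: pd.Series) -> float:
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    agg = (aligned.data.groupby(["group", "rel_t_min"])["norm_area"]
           .agg(n="size", mean="mean", sem=_sem)
           .reset_index())
    agg["n"] = agg["n"].astype(int)
    return agg


def _sine(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    c, a, T, phi = params
    return c + a * np.sin(2 * np.pi * t / T + phi)


def _fft_seed(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Initial (amplitude, period, phase) from the dominant non-DC
    discrete-Fourier component."""
    n = len(y)
    dt = t[1] - t[0]
    Y = np.fft.rfft(y - y.mean())
    if len(Y) < 2:
        return 0.0, 2 * dt, 0.0
    k = int(np.argmax(np.abs(Y[1:]))) + 1
    freq = k / (n * dt)
    amp = 2 * np.abs(Y[k]) / n
    phase = float(np.angle(Y[k]) + np.pi / 2)
    return float(amp), float(1 / freq), phase


def fit_sine(
    y: np.ndarray,
    dt: float,
    *,
    t: np.ndarray | None = None,
    max_nfev: int = 500,
    xtol: float = 1e-10,
) -> SineFit:
    """Nonlinear least-squares fit of y = c + A sin(2 pi t / T + phi).

    Initialized from the dominant discrete-Fourier component; the period
    is constrained to [2 dt, 2 * span]. Amplitude is reported as |A|.
    If the solver fails, the fit is flagged unconverged and the amplitude
    falls back to half the peak-to-trough range.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise ValueError("sine fit needs >= 4 samples")
    if t is None:
        t = np.arange(len(y)) * dt
    else:
        t = np.asarray(t, dtype=float)
    span = t[-1] - t[0]
    t_lo, t_hi = 2 * dt, 2 * span

    ptp = float(y.max() - y.min())
    if ptp < 1e-12:  # constant trace: exact degenerate answer
        return SineFit(0.0, t_hi, 0.0, float(y.mean()), 1.0, True)

    a0, T0, phi0 = _fft_seed(t, y)
    seeds = [(max(a0, 1e-6 * ptp), np.clip(T0, t_lo, t_hi), phi0)]
    # fallback seeds for traces whose dominant period is off-bin
    for T_alt in (span, span / 2, span / 3):
        if t_lo <= T_alt <= t_hi:
            seeds.append((ptp / 2, T_alt, 0.0))

    def _jac(p: np.ndarray, t: np.ndarray) -> np.ndarray:
        c, a, T, phi = p
        arg = 2 * np.pi * t / T + phi
        cos = np.cos(arg)
        return np.column_stack([np.ones_like(t), np.sin(arg),
                                -a * cos * 2 * np.pi * t / T**2, a * cos])

    ss_tot = float(((y - y.mean()) ** 2).sum())
    best = None
    for a_s, T_s, phi_s in seeds:
        try:
            sol = least_squares(
                lambda p: _sine(p, t) - y, jac=lambda p: _jac(p, t),
                x0=[y.mean(), a_s, T_s, phi_s],
                bounds=([-np.inf, -np.inf, t_lo, -np.inf],
                        [np.inf, np.inf, t_hi, np.inf]),
                xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=max_nfev)
        except Exception:
            continue
        cost = float(sol.cost)
        if best is None or cost < best[0]:
            best = (cost, sol)
        # stop once a seed explains half the variance; the remaining
        # seeds only rescue off-bin dominant periods
        if cost <= 0.25 * ss_tot:
            break
    if best is None:
        return SineFit(ptp / 2, t_hi, 0.0, float(y.mean()), 0.0, False)

    sol = best[1]
    c, a, T, phi = sol.x
    if a < 0:  # fold the sign into the phase
        a, phi = -a, phi + np.pi
    phi = float(np.mod(phi + np.pi, 2 * np.pi) - np.pi)
    ss_res = float(((_sine([c, abs(a), T, phi], t) - y) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SineFit(float(abs(a)), float(T), phi, float(c), float(r2),
                   bool(sol.success))


def fit_all(traces: list[CellTrace], *, interphase_window: bool = False,
            pre_anaphase_margin: float = 30.0) -> pd.DataFrame:
    """Sine-fit every trace with >= 4 samples; returns a per-cell table.

    By default mitotic traces are fitted over their full span, event
    included (the amplitude contrast is oscillation magnitude, and the
    constriction event dominates the mitotic amplitude). With
    ``interphase_window=True`` mitotic traces are truncated to samples
    earlier than ``pre_anaphase_margin`` min before anaphase.
    """
    rows, skipped = [], []
    for tr in traces:
        y = normalize_trace(tr)
        t = tr.t
        if interphase_window and tr.is_mitotic:
            keep = t < tr.anaphase_t - pre_anaphase_margin
            t, y = t[keep], y[keep]
            y = y / y.mean() if len(y) else y
        if len(y) < 4:
            skipped.append(tr.cell_id)
            continue
        fit = fit_sine(y, tr.dt, t=t)
        rows.append({"cell_id": tr.cell_id,
                     "group": "mitotic" if tr.is_mitotic else "non-mitotic",
                     **fit.to_dict()})
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def pre_anaphase_test(aligned: AlignedTraceSet, lag: float = 30.0) -> StatResult:
    """Paired t-test of mitotic normalized area at T-lag vs T0.

    Cells lacking a sample at T-lag are excluded and counted in
    ``n_excluded``. Zero variance of the paired differences is reported as
    degenerate (p -> 0 when the common difference is nonzero).
    """
    mit = aligned.data[aligned.data["group"] == "mitotic"]
    wide = mit.pivot_table(index="cell_id", columns="rel_t_min",
                           values="norm_area")
    for col in (0.0, -lag):
        if col not in wide.columns:
            raise ValueError(f"no mitotic samples at rel_t = {col}")
    pairs = wide[[-lag, 0.0]].dropna()
    if len(pairs) < 2:
        raise ValueError("fewer than 2 cells with samples at both T0 and T-lag")
    res = t_test(pairs[-lag], pairs[0.0], paired=True,
                 labels=(f"T-{lag:g}", "T0"))
    res.n_excluded = len(wide) - len(pairs)
    return res


def compare_amplitudes(fits: pd.DataFrame) -> StatResult:
    """Unpaired two-sided t-test of sine amplitudes, mitotic vs
    non-mitotic (the headline pulse-amplitude contrast)."""
    mit = fits.loc[fits["group"] == "mitotic", "amplitude"].to_numpy()
    non = fits.loc[fits["group"] == "non-mitotic", "amplitude"].to_numpy()
    if len(mit) < 2 or len(non) < 2:
        raise ValueError("need >= 2 fitted amplitudes per group")
    return t_test(mit, non, labels=("mitotic", "non-mitotic"))
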