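"""Synthetic pupariation experiments with known ground truth.

The generator emulates the study design the analysis assumes: 11 sucrose
concentrations (0–1.5 M in 0.15 M steps) x 5 replicate vials x 50 embryos,
scored on an 8 h observation grid. Individual pupariation times are drawn
by inverse-transform sampling from the normalized Gompertz curve treated as
a CDF, whose parameters follow bilinear reaction norms of concentration:
synchrony s_dvp(E) decreases with a kink at the stress threshold, timing
t_mid(E) increases, and binomial viability declines linearly across the
grid. The ground-truth parameter maps travel with every generated dataset
so recovery can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._exceptions import ValidationError
from .data_io import VialSeries, write_counts_csv
from .primary import gompertz_lag_from_tmid, gompertz_tmid

__all__ = [
    "BilinearNorm",
    "SyntheticTruth",
    "build_truth",
    "sample_pupariation_times",
    "simulate_vial",
    "generate_experiment",
    "downsample_schedule",
    "DEFAULT_SCHEDULE_OFFSETS",
]

_E = np.e

# daily clock offsets (hours past 9 a.m., which is time 0 on the grid)
DEFAULT_SCHEDULE_OFFSETS = {3: (0.0, 8.0, 16.0), 2: (0.0, 8.0), 1: (0.0,)}


@dataclass(frozen=True)
class BilinearNorm:
    """Two-segment reaction norm; the second intercept follows by continuity."""

    a1: float
    b1: float
    a2: float
    x_c: float

    @property
    def b2(self) -> float:
        return self.b1 + (self.a1 - self.a2) * self.x_c

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x <= self.x_c, self.a1 * x + self.b1, self.a2 * x + self.b2)
        return out if out.ndim else float(out)


# Default truth: synchrony norm uses the fitted stress-response estimates
# (intercept 0.0427, slopes -0.0466 / -0.0053, kink at 0.581 M); the timing
# norm is anchored at t_mid(0) = 121.7 h and t_mid(1.5 M) = 271.5 h with a
# kink at 0.524 M; viability declines linearly 0.85 -> 0.55 across the grid.
_DEFAULT_SDVP = BilinearNorm(a1=-0.0466, b1=0.0427, a2=-0.0053, x_c=0.581)
_DEFAULT_TMID = BilinearNorm(a1=40.0, b1=121.7, a2=132.0, x_c=0.524)


@dataclass(frozen=True)
class SyntheticTruth:
    """Fully resolved ground truth for one synthetic experiment."""

    concentrations: tuple = tuple(np.round(np.arange(11) * 0.15, 4))
    sdvp_norm: BilinearNorm = _DEFAULT_SDVP
    tmid_norm: BilinearNorm = _DEFAULT_TMID
    viability_intercept: float = 0.85
    viability_slope: float = -0.2
    n_vials: int = 5
    n_embryos: int = 50
    obs_interval_h: float = 8.0
    seed: int = 0

    def s_dvp(self, E):
        return self.sdvp_norm(E)

    def t_mid(self, E):
        return self.tmid_norm(E)

    def lag(self, E):
        """Lag implied by the timing and synchrony norms via the closed form."""
        return gompertz_lag_from_tmid(self.s_dvp(E), self.t_mid(E))

    def viability(self, E):
        return self.viability_intercept + self.viability_slope * np.asarray(E, float)

    def to_dict(self):
        d = asdict(self)
        d["concentrations"] = [float(c) for c in self.concentrations]
        return d


def build_truth(config: dict | None = None) -> SyntheticTruth:
    """Resolve a config mapping into a validated :class:`SyntheticTruth`.

    Recognized keys mirror the dataclass fields; ``sdvp_norm`` / ``tmid_norm``
    may be dicts with keys a1, b1, a2, x_c. Validates that s_dvp, t_mid and
    viability are positive (viability <= 1) at every grid concentration.
    """
    config = dict(config or {})
    for key in ("sdvp_norm", "tmid_norm"):
        if key in config and isinstance(config[key], dict):
            config[key] = BilinearNorm(**config[key])
    if "concentrations" in config:
        config["concentrations"] = tuple(float(c) for c in config["concentrations"])
    truth = SyntheticTruth(**config)
    E = np.asarray(truth.concentrations)
    if np.any(E < 0) or np.any(np.diff(E) <= 0):
        raise ValidationError("concentration grid must be non-negative and increasing")
    for name, vals in (("s_dvp", truth.s_dvp(E)), ("t_mid", truth.t_mid(E))):
        if np.any(np.asarray(vals) <= 0):
            raise ValidationError(f"truth {name}(E) must be positive on the whole grid")
    v = np.asarray(truth.viability(E))
    if np.any(v <= 0) or np.any(v > 1):
        raise ValidationError("truth viability must lie in (0, 1] on the whole grid")
    return truth


def sample_pupariation_times(n, s_dvp, lam, seed=None, rng=None):
    """Inverse-CDF sample of individual pupariation times.

    The normalized Gompertz curve is read as the CDF of an individual's
    pupariation time; inverting y(t) = u gives
    ``t(u) = lam + (1 - ln(-ln u)) / (e * s_dvp)`` for u ~ Uniform(0, 1).
    The median of the distribution is exactly the Gompertz t_mid.
    """
    if s_dvp <= 0:
        raise ValueError("s_dvp must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(int(n))
    return lam + (1.0 - np.log(-np.log(u))) / (_E * s_dvp)


def _vial_seed(root_seed, conc_index, vial_index):
    # deterministic per-vial stream derived from (root, concentration, vial)
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(conc_index, vial_index))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_vial(concentration, truth: SyntheticTruth, vial_seed, vial_id=None) -> VialSeries:
    """Simulate one vial: binomial survival, Gompertz event times, 8 h censoring.

    The observation grid runs from 0 h to 24 h past the last event (one
    trailing day guarantees the final cumulative count is observed), in
    steps of ``truth.obs_interval_h``. A vial with zero survivors yields an
    all-zero two-point series.
    """
    E = float(concentration)
    rng = np.random.default_rng(vial_seed)
    n_survivors = int(rng.binomial(truth.n_embryos, float(truth.viability(E))))
    dt = truth.obs_interval_h
    if n_survivors == 0:
        times = np.array([0.0, dt])
        counts = np.zeros(2, dtype=int)
    else:
        events = sample_pupariation_times(
            n_survivors, truth.s_dvp(E), truth.lag(E), rng=rng
        )
        t_end = (np.ceil((events.max() + 24.0) / dt)) * dt
        times = np.arange(0.0, t_end + 0.5 * dt, dt)
        counts = np.searchsorted(np.sort(events), times, side="right")
    return VialSeries(
        vial_id=vial_id or f"E{E:g}_s{vial_seed}",
        concentration=E,
        n_embryos=truth.n_embryos,
        times=times,
        cum_counts=counts,
    )


def generate_experiment(truth: SyntheticTruth, out_dir=None):
    """Generate the full design: ``n_vials`` per grid concentration.

    Per-vial seeds are derived from the root seed by (concentration index,
    vial index), so any subset of vials is reproducible in isolation.
    When ``out_dir`` is given, writes ``counts.csv`` (data_io dialect) and
    a ``truth.json`` sidecar.

    Returns ``(vials, truth)``.
    """
    vials = []
    for ci, E in enumerate(truth.concentrations):
        for vi in range(truth.n_vials):
            seed = _vial_seed(truth.seed, ci, vi)
            vials.append(
                simulate_vial(E, truth, seed, vial_id=f"c{ci:02d}_v{vi}")
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts_csv(out / "counts.csv", vials)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2)
    return vials, truth


def downsample_schedule(series: VialSeries, per_day, clock_offsets_h=None) -> VialSeries:
    """Thin an 8 h observation grid to a reduced daily schedule.

    Keeps observations whose time-of-day (time mod 24) is in the offset
    set: three observations per day keeps {0, 8, 16} (the full grid), two
    keeps {0, 8} (9 a.m. and 5 p.m.), one keeps {0} (9 a.m. only).
    Cumulative counts at retained times are unchanged — the schedule only
    removes observation times.
    """
    if clock_offsets_h is None:
        if per_day not in DEFAULT_SCHEDULE_OFFSETS:
            raise ValueError("per_day must be 1, 2 or 3")
        clock_offsets_h = DEFAULT_SCHEDULE_OFFSETS[per_day]
    offsets = np.asarray(clock_offsets_h, dtype=float)
    step = series_grid_step(series)
    if np.any(offsets % step != 0):
        raise ValueError(f"offsets {clock_offsets_h} do not lie on the {step:g} h grid")
    keep = np.isin(np.round(series.times % 24.0, 9), np.round(offsets, 9))
    if not np.any(keep):
        raise ValueError("schedule retains no observations")
    return VialSeries(
        vial_id=series.vial_id,
        concentration=series.concentration,
        n_embryos=series.n_embryos,
        times=series.times[keep],
        cum_counts=series.cum_counts[keep],
        response=series.response,
    )


def series_grid_step(series: VialSeries) -> float:
    """Observation-grid step of a series (smallest time difference)."""
    if series.times.size < 2:
        return 8.0
    return float(np.min(np.diff(series.times)))
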