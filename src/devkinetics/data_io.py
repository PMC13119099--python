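"""Vial-level count series, replicate aggregation and curve normalization.

The experimental unit is a vial seeded with a known number of embryos and
scored repeatedly for the cumulative number of pupae (or eclosed adults).
Five replicate vials per sucrose concentration are averaged into one
treatment-level growth curve, which is then normalized by its final count so
that every curve runs from 0 to exactly 1 — the scale on which the sigmoid
models are fitted.

Times are hours since the midpoint of the 2 h embryo-collection window.
Concentrations are sucrose molarity (mol/L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import EmptyCurveError, FormatError, ValidationError

__all__ = [
    "VialSeries",
    "TreatmentCurve",
    "NormalizedCurve",
    "read_counts_csv",
    "write_counts_csv",
    "aggregate_replicates",
    "normalize_curve",
]

REQUIRED_COLUMNS = ("vial_id", "concentration_M", "n_embryos", "time_h", "cum_pupae")


@dataclass
class VialSeries:
    """One vial's cumulative count time series.

    Parameters
    ----------
    vial_id : str
        Unique vial label.
    concentration : float
        Sucrose molarity of the medium, mol/L (>= 0).
    n_embryos : int
        Embryos seeded into the vial (> 0).
    times : ndarray
        Observation times in hours, strictly increasing.
    cum_counts : ndarray
        Cumulative pupae (or adults) at each time; non-decreasing integers
        bounded by ``n_embryos``.
    response : str
        ``"pupae"`` or ``"adults"``.
    """

    vial_id: str
    concentration: float
    n_embryos: int
    times: np.ndarray
    cum_counts: np.ndarray
    response: str = "pupae"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cum_counts = np.asarray(self.cum_counts)
        if self.concentration < 0:
            raise ValidationError(f"vial {self.vial_id}: negative concentration")
        if self.n_embryos <= 0:
            raise ValidationError(f"vial {self.vial_id}: n_embryos must be positive")
        if self.times.ndim != 1 or self.times.shape != self.cum_counts.shape:
            raise ValidationError(f"vial {self.vial_id}: times/counts shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"vial {self.vial_id}: times not strictly increasing")
        drops = np.nonzero(np.diff(self.cum_counts) < 0)[0]
        if drops.size:
            t_bad = self.times[drops[0] + 1]
            raise ValidationError(
                f"vial {self.vial_id}: cumulative count decreases at t={t_bad:g} h"
            )
        if np.any(self.cum_counts < 0) or np.any(self.cum_counts > self.n_embryos):
            raise ValidationError(
                f"vial {self.vial_id}: counts outside [0, n_embryos={self.n_embryos}]"
            )

    @property
    def final_count(self):
        return int(self.cum_counts[-1])


@dataclass
class TreatmentCurve:
    """Replicate-averaged cumulative curve for one concentration."""

    concentration: float
    times: np.ndarray
    mean_counts: np.ndarray
    n_replicates: int
    viability: float
    response: str = "pupae"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean_counts = np.asarray(self.mean_counts, dtype=float)
        if np.any(np.diff(self.mean_counts) < -1e-9):
            raise ValidationError(
                f"treatment {self.concentration} M: mean counts decrease"
            )
        if not 0.0 <= self.viability <= 1.0:
            raise ValidationError(
                f"treatment {self.concentration} M: viability {self.viability} not in [0,1]"
            )

    @property
    def y_max_count(self) -> float:
        """Final mean count — the normalization denominator."""
        return float(self.mean_counts[-1])


@dataclass
class NormalizedCurve:
    """Cumulative curve rescaled by its final value: y = y_obs / y_max in [0, 1]."""

    concentration: float
    times: np.ndarray
    y: np.ndarray
    response: str = "pupae"
    n_individuals: int | None = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.size == 0 or abs(self.y[-1] - 1.0) > 1e-12:
            raise ValidationError(
                f"normalized curve at {self.concentration} M must end at exactly 1"
            )
        if self.y[0] < 0 or np.any(np.diff(self.y) < -1e-12):
            raise ValidationError(
                f"normalized curve at {self.concentration} M is not non-decreasing in [0,1]"
            )


def read_counts_csv(path) -> list[VialSeries]:
    """Read a long-format counts CSV into a list of :class:`VialSeries`.

    Required columns: ``vial_id, concentration_M, n_embryos, time_h,
    cum_pupae``; an optional ``cum_adults`` column yields a second series
    per vial with ``response="adults"``. Rows are sorted by time within each
    vial before validation.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_adults = "cum_adults" in df.columns and df["cum_adults"].notna().all()
    out: list[VialSeries] = []
    for vial_id, grp in df.groupby("vial_id", sort=True):
        grp = grp.sort_values("time_h")
        conc = float(grp["concentration_M"].iloc[0])
        n_emb = int(grp["n_embryos"].iloc[0])
        out.append(
            VialSeries(
                vial_id=str(vial_id),
                concentration=conc,
                n_embryos=n_emb,
                times=grp["time_h"].to_numpy(dtype=float),
                cum_counts=grp["cum_pupae"].to_numpy(),
                response="pupae",
            )
        )
        if has_adults:
            out.append(
                VialSeries(
                    vial_id=str(vial_id),
                    concentration=conc,
                    n_embryos=n_emb,
                    times=grp["time_h"].to_numpy(dtype=float),
                    cum_counts=grp["cum_adults"].to_numpy(),
                    response="adults",
                )
            )
    return out


def write_counts_csv(path, vials: list[VialSeries]) -> None:
    """Write vial series back to the long CSV dialect read by :func:`read_counts_csv`."""
    pupae = {v.vial_id: v for v in vials if v.response == "pupae"}
    adults = {v.vial_id: v for v in vials if v.response == "adults"}
    rows = []
    for vial_id in sorted(pupae):
        v = pupae[vial_id]
        a = adults.get(vial_id)
        for i, t in enumerate(v.times):
            row = {
                "vial_id": v.vial_id,
                "concentration_M": v.concentration,
                "n_embryos": v.n_embryos,
                "time_h": t,
                "cum_pupae": int(v.cum_counts[i]),
            }
            if a is not None:
                row["cum_adults"] = int(a.cum_counts[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _carry_forward(times_union, times, counts):
    # cumulative counts are step functions: carry the last seen value forward
    idx = np.searchsorted(times, times_union, side="right") - 1
    out = np.where(idx >= 0, counts[np.clip(idx, 0, None)], 0)
    return out.astype(float)


def aggregate_replicates(
    vials: list[VialSeries], concentration: float, *, response: str = "pupae"
) -> TreatmentCurve:
    """Average replicate vials at one concentration into a single growth curve.

    When replicate grids differ, the union of observation times is used and
    each vial's cumulative count is carried forward between its own
    observations (a cumulative count is a step function, so this introduces
    no interpolation assumption).

    Viability is the mean over vials of (final count / embryos seeded).
    """
    sel = [
        v
        for v in vials
        if v.response == response and np.isclose(v.concentration, concentration)
    ]
    if not sel:
        raise ValueError(f"no vials at concentration {concentration} M")
    n_embryos = {v.n_embryos for v in sel}
    if len(n_embryos) > 1:
        warnings.warn(
            f"inconsistent n_embryos across vials at {concentration} M; "
            "using per-vial denominators for viability",
            stacklevel=2,
        )
    grid = np.unique(np.concatenate([v.times for v in sel]))
    stacked = np.vstack([_carry_forward(grid, v.times, v.cum_counts) for v in sel])
    mean_counts = stacked.mean(axis=0)
    viability = float(np.mean([v.final_count / v.n_embryos for v in sel]))
    return TreatmentCurve(
        concentration=concentration,
        times=grid,
        mean_counts=mean_counts,
        n_replicates=len(sel),
        viability=viability,
        response=response,
    )


def normalize_curve(curve: TreatmentCurve) -> NormalizedCurve:
    """Rescale a treatment curve to y = mean_counts / final count, ending at 1."""
    if curve.y_max_count <= 0:
        raise EmptyCurveError(
            f"no survivors at {curve.concentration} M: cannot normalize an all-zero curve"
        )
    y = curve.mean_counts / curve.y_max_count
    y[-1] = 1.0  # guard against float round-off in the division
    return NormalizedCurve(
        concentration=curve.concentration,
        times=curve.times,
        y=y,
        response=curve.response,
    )
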