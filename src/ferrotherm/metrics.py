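"""Treatment summaries: therapeutic-sphere radius, damaged volume, dose response.

The clinical headline of a hyperthermia simulation is the "therapeutic
sphere": the central region whose temperature lies in the hyperthermic band
40-45 C.  Its outer radius r0 is reported as a function of the administered
dose (the ratio of infusate concentration to the maximum clinically
accepted concentration) for spherical and cubic particles of equal volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RadialGrid
from .scenario import Scenario

__all__ = [
    "therapeutic_radius",
    "damaged_volume_fraction",
    "DoseResponseTable",
    "dose_sweep",
    "scenario_for_shape",
]


def _segments(radii: np.ndarray, values: np.ndarray, inner_radius: float):
    """Piecewise-linear profile extended flat to the inner boundary."""
    r = np.concatenate([[inner_radius], np.asarray(radii, dtype=float)])
    v = np.concatenate([[values[0]], np.asarray(values, dtype=float)])
    return r, v


def _first_down_crossing(r: np.ndarray, v: np.ndarray, level: float,
                         start: float) -> float | None:
    """Radius >= start where the linear-interpolated profile falls below level."""
    for i in range(len(r) - 1):
        r0, r1, v0, v1 = r[i], r[i + 1], v[i], v[i + 1]
        if r1 <= start:
            continue
        if r0 < start:  # clip the segment to begin at `start`
            v0 = v0 + (v1 - v0) * (start - r0) / (r1 - r0)
            r0 = start
        if v0 < level:
            return r0
        if v1 < level:  # crossing inside this segment
            return r0 + (v0 - level) / (v0 - v1) * (r1 - r0)
    return None


def therapeutic_radius(radii, temperature, band, inner_radius: float | None = None,
                       mode: str = "band_shell") -> tuple[float, float]:
    """Radius r0 of the therapeutic sphere, plus the ablative core radius.

    The profile is taken piecewise-linear between cell centres (flat inward
    of the first centre).  ``r_ablative`` is the outer radius of the
    contiguous supra-band core (T > T_high) at the inner boundary, 0 if
    none.  In ``band_shell`` mode r0 is the outer radius of the contiguous
    in-band region that starts where the core ends; in ``ge_lower`` mode
    the upper bound is ignored and r0 is simply where T first falls below
    T_low.  Returns (r0, r_ablative), both 0 when nothing qualifies.
    """
    t_low, t_high = band
    if not t_low < t_high:
        raise ValueError(f"therapeutic band must be ordered (got {band})")
    radii = np.asarray(radii, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if inner_radius is None:
        inner_radius = radii[0]
    r, v = _segments(radii, temperature, inner_radius)

    # ablative core: contiguous T > T_high from the inner boundary
    if v[0] > t_high:
        cross = _first_down_crossing(r, v, t_high, inner_radius)
        r_abl = cross if cross is not None else float(r[-1])
    else:
        r_abl = 0.0

    start = r_abl if r_abl > 0 else inner_radius
    v_start = float(np.interp(start, r, v))
    if mode == "ge_lower":
        if v_start < t_low:
            return (r_abl, r_abl) if r_abl > 0 else (0.0, 0.0)
        cross = _first_down_crossing(r, v, t_low, start)
        r0 = cross if cross is not None else float(r[-1])
        return r0, r_abl
    if mode != "band_shell":
        raise ValueError(f"unknown r0 mode {mode!r}")

    if v_start < t_low:
        # band is never entered contiguously from the centre
        return (r_abl, r_abl) if r_abl > 0 else (0.0, 0.0)
    low_cross = _first_down_crossing(r, v, t_low, start)
    r_low = low_cross if low_cross is not None else float(r[-1])
    if r_abl == 0.0:
        # also stop if the profile rises above the band before falling below it
        up = _first_up_crossing(r, v, t_high, start)
        if up is not None and up < r_low:
            r_low = up
    return r_low, r_abl


def _first_up_crossing(r: np.ndarray, v: np.ndarray, level: float,
                       start: float) -> float | None:
    return _first_down_crossing(r, -v, -level, start)


def damaged_volume_fraction(undamaged_fraction, grid: RadialGrid,
                            threshold: float, tumor_radius: float) -> float:
    """Fraction of the tumor volume with theta below the survival threshold.

    The theta profile is interpolated linearly between cell centres and the
    sub-threshold region integrated exactly (shell volumes), relative to
    the tumor volume minus the needle cavity.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1) (got {threshold})")
    theta = np.asarray(undamaged_fraction, dtype=float)
    r, v = _segments(grid.centers, theta, grid.inner_radius)
    # append a flat tail out to the domain edge so the last cell is covered
    r = np.concatenate([r, [grid.outer_radius]])
    v = np.concatenate([v, [v[-1]]])

    lo, hi = grid.inner_radius, tumor_radius
    total = hi**3 - lo**3
    if total <= 0:
        raise ValueError("tumor radius must exceed the needle radius")
    damaged = 0.0
    for i in range(len(r) - 1):
        a, b = max(r[i], lo), min(r[i + 1], hi)
        if b <= a:
            continue
        va = np.interp(a, r, v)
        vb = np.interp(b, r, v)
        below_a, below_b = va < threshold, vb < threshold
        if below_a and below_b:
            damaged += b**3 - a**3
        elif below_a or below_b:
            # linear profile crosses the threshold once inside (a, b)
            x = a + (threshold - va) / (vb - va) * (b - a)
            if below_a:
                damaged += x**3 - a**3
            else:
                damaged += b**3 - x**3
    return damaged / total


@dataclass
class DoseResponseTable:
    """r0 (and companions) per dose ratio and particle shape."""

    dose_ratios: np.ndarray  # in (0, 1]
    shapes: list
    r0: np.ndarray  # (n_doses, n_shapes), m
    r_ablative: np.ndarray  # (n_doses, n_shapes), m
    damaged_fraction: np.ndarray  # (n_doses, n_shapes)
    peak_temperature: np.ndarray  # (n_doses, n_shapes), K
    failures: list  # (dose, shape, message) for runs that errored

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, dose in enumerate(self.dose_ratios):
            for j, shape in enumerate(self.shapes):
                rows.append({
                    "dose_ratio": dose,
                    "shape": shape,
                    "r0_mm": self.r0[i, j] * 1e3,
                    "r_ablative_mm": self.r_ablative[i, j] * 1e3,
                    "damaged_fraction": self.damaged_fraction[i, j],
                    "peak_T_C": self.peak_temperature[i, j] - 273.15,
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def monotone_in_dose(self, tolerance: float = 0.0) -> dict:
        """Per shape: is r0 non-decreasing with dose?"""
        out = {}
        for j, shape in enumerate(self.shapes):
            diffs = np.diff(self.r0[:, j])
            out[str(shape)] = bool(np.all(diffs >= -tolerance))
        return out


def scenario_for_shape(base: Scenario, shape: str) -> Scenario:
    """Swap the particle for its equal-volume counterpart of ``shape``.

    Keeps everything else identical, so paired runs isolate the shape
    effect.  The shape-specific effective anisotropy constants of the
    shipped presets are applied when converting.
    """
    from .magnetics import cube_variant, equal_volume_cube_edge
    from .scenario import _K_CUBE, _K_SPHERE

    p = base.particle
    if p.shape == shape:
        return base
    if shape == "cube":
        new_p = cube_variant(p, anisotropy_constant=_K_CUBE)
    elif shape == "sphere":
        new_p = dataclasses.replace(
            p, shape="sphere",
            characteristic_size=p.volume_equivalent_radius,
            anisotropy_constant=_K_SPHERE)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return base.replace(particle=new_p)


def dose_sweep(base: Scenario, dose_ratios, shapes=("sphere", "cube")) -> DoseResponseTable:
    """Run the full protocol per (dose, shape) and tabulate r0.

    The dose ratio scales the infusate concentration C_max.  Failed runs
    are recorded and the sweep continues (their entries are NaN).
    """
    from .bioheat import simulate

    ratios = np.asarray(list(dose_ratios), dtype=float)
    if ratios.size == 0 or np.any(ratios <= 0) or np.any(ratios > 1):
        raise ValueError("dose ratios must lie in (0, 1]")
    shapes = list(shapes)
    shape_fill = (len(ratios), len(shapes))
    r0 = np.full(shape_fill, np.nan)
    r_abl = np.full(shape_fill, np.nan)
    damaged = np.full(shape_fill, np.nan)
    peak = np.full(shape_fill, np.nan)
    failures = []
    for j, shape in enumerate(shapes):
        shaped = scenario_for_shape(base, shape)
        for i, ratio in enumerate(ratios):
            scen = shaped.replace(infusion=dataclasses.replace(
                shaped.infusion,
                max_concentration=base.infusion.max_concentration * ratio))
            try:
                res = simulate(scen)
            except Exception as exc:  # keep sweeping, mark the failure
                failures.append((float(ratio), shape, str(exc)))
                continue
            r0[i, j] = res.therapeutic_radius
            r_abl[i, j] = res.ablative_radius
            damaged[i, j] = res.damaged_fraction
            peak[i, j] = res.peak_temperature
    return DoseResponseTable(dose_ratios=ratios, shapes=shapes, r0=r0,
                             r_ablative=r_abl, damaged_fraction=damaged,
                             peak_temperature=peak, failures=failures)
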