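"""F-actin co-sedimentation analysis: fraction bound and the Hill fit.

High-speed pelleting separates F-actin (and anything bound to it) from
free protein; the binder's supernatant/pellet band intensities at a
series of actin concentrations give a saturation curve. After
subtracting the fraction that pellets nonspecifically without actin, the
fraction bound is fit to the Hill equation

    f(A) = plateau · A^h / (K_d^h + A^h)

by nonlinear least squares with multi-start initialization (Hill fits at
small n are multimodal). Low-speed pelleting, which only sediments
large bundled assemblies, is summarized as the fraction of actin
pelleted per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthetic_data import hill_curve

__all__ = [
    "HillFitResult",
    "validate_binding_dataset",
    "fraction_bound",
    "fit_hill",
    "lowspeed_fraction_pelleted",
]

REQUIRED_COLUMNS = (
    "actin_conc_um",
    "replicate",
    "supernatant_intensity",
    "pellet_intensity",
)

_KD_BOUNDS = (1e-6, 1e4)
_H_BOUNDS = (0.05, 20.0)
_PLATEAU_BOUNDS = (1e-6, 1.5)


def validate_binding_dataset(ds: pd.DataFrame, require_zero: bool = True) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in ds.columns]
    if missing:
        raise ValueError(f"binding dataset missing columns: {missing}")
    total = ds["supernatant_intensity"] + ds["pellet_intensity"]
    if (total <= 0).any():
        raise ValueError("each row needs supernatant + pellet intensity > 0")
    if (ds["actin_conc_um"] < 0).any():
        raise ValueError("actin concentrations must be nonnegative")
    if require_zero and not (ds["actin_conc_um"] == 0).any():
        raise ValueError("dataset needs a zero-actin row for the nonspecific correction")


def fraction_bound(ds: pd.DataFrame, renormalize: bool = True) -> pd.DataFrame:
    """Fraction of binder bound to F-actin per reaction.

    Raw pellet fraction p = pellet/(pellet+supernatant); the mean raw
    pellet fraction of the zero-actin reactions, p₀, is the nonspecific
    correction. Default (``renormalize=True``): (p − p₀)/(1 − p₀),
    clipped to [0, 1], so full binding maps to 1; ``renormalize=False``
    gives the plain subtraction p − p₀ (the other reading of
    "nonspecific pelleting was subtracted"). Zero-actin rows are dropped
    from the output.
    """
    validate_binding_dataset(ds)
    p = ds["pellet_intensity"] / (ds["pellet_intensity"] + ds["supernatant_intensity"])
    zero = ds["actin_conc_um"] == 0
    p0 = float(p[zero].mean())
    if p0 >= 1:
        raise ValueError("nonspecific pellet fraction is 1: no dynamic range")
    corrected = (p - p0) / (1 - p0) if renormalize else p - p0
    out = ds.loc[~zero, ["actin_conc_um", "replicate"]].copy()
    out["fraction_bound"] = np.clip(corrected[~zero], 0.0, 1.0)
    return out.reset_index(drop=True)


@dataclass
class HillFitResult:
    """Fitted cooperative-binding parameters and diagnostics."""

    kd_um: float
    h: float
    plateau: float
    residual_sum_squares: float
    converged: bool
    plateau_mode: str
    n_points: int
    kd_ci: tuple[float, float] | None = None
    h_ci: tuple[float, float] | None = None
    plateau_ci: tuple[float, float] | None = None

    def predict(self, conc_um):
        return hill_curve(conc_um, self.kd_um, self.h, self.plateau)


def _fit_once(conc, frac, plateau_mode, kd0, h0):
    if plateau_mode == "fixed_1":
        def resid(p):
            return hill_curve(conc, p[0], p[1], 1.0) - frac

        x0 = [kd0, h0]
        lb = [_KD_BOUNDS[0], _H_BOUNDS[0]]
        ub = [_KD_BOUNDS[1], _H_BOUNDS[1]]
    else:
        def resid(p):
            return hill_curve(conc, p[0], p[1], p[2]) - frac

        x0 = [kd0, h0, max(float(frac.max()), 0.5)]
        lb = [_KD_BOUNDS[0], _H_BOUNDS[0], _PLATEAU_BOUNDS[0]]
        ub = [_KD_BOUNDS[1], _H_BOUNDS[1], _PLATEAU_BOUNDS[1]]
    x0 = np.clip(x0, lb, ub)
    return least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)


def _best_fit(conc, frac, plateau_mode):
    kd_starts = (float(conc.min()), float(np.exp(np.mean(np.log(conc)))), float(conc.max()))
    best = None
    ok = False
    for kd0 in kd_starts:
        for h0 in (1.0, 2.0, 4.0):
            res = _fit_once(conc, frac, plateau_mode, kd0, h0)
            if best is None or res.cost < best.cost:
                best = res
            ok = ok or res.success
    return best, ok


def fit_hill(
    points,
    plateau_mode: str = "fixed_1",
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> HillFitResult:
    """Fit the Hill equation to (concentration, fraction bound) points.

    ``points`` is any structure coercible to two columns (e.g. the output
    of :func:`fraction_bound` or an (n, 2) array). ``plateau_mode``
    ``fixed_1`` pins the saturation plateau at 1; ``free`` floats it in
    (0, 1.5]. Optional bootstrap (resampling points with replacement
    within each concentration, ``n_bootstrap`` draws, seeded) gives
    percentile 95% confidence intervals.
    """
    if isinstance(points, pd.DataFrame):
        conc = np.asarray(points["actin_conc_um"], dtype=float)
        frac = np.asarray(points["fraction_bound"], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        conc, frac = arr[:, 0], arr[:, 1]
    if plateau_mode not in ("fixed_1", "free"):
        raise ValueError("plateau_mode must be 'fixed_1' or 'free'")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("fit concentrations must be positive (drop the zero control)")
    if np.any((frac < -1e-9) | (frac > 1 + 1e-9)):
        raise ValueError("fractions bound must lie in [0, 1]")
    if np.allclose(frac, frac[0]):
        raise ValueError("degenerate data: all fractions equal")

    best, ok = _best_fit(conc, frac, plateau_mode)
    params = best.x
    plateau = 1.0 if plateau_mode == "fixed_1" else float(params[2])
    result = HillFitResult(
        kd_um=float(params[0]),
        h=float(params[1]),
        plateau=plateau,
        residual_sum_squares=float(2 * best.cost),
        converged=bool(ok),
        plateau_mode=plateau_mode,
        n_points=len(conc),
    )
    if not ok:
        raise RuntimeError("Hill fit failed to converge from every start")

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        groups = {c: np.nonzero(conc == c)[0] for c in np.unique(conc)}
        kds, hs, plats = [], [], []
        for _ in range(n_bootstrap):
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups.values()]
            )
            bc, bf = conc[idx], frac[idx]
            if np.allclose(bf, bf[0]):
                continue
            b, bok = _best_fit(bc, bf, plateau_mode)
            if not bok:
                continue
            kds.append(b.x[0])
            hs.append(b.x[1])
            plats.append(b.x[2] if plateau_mode == "free" else 1.0)
        if kds:
            result.kd_ci = tuple(np.percentile(kds, [2.5, 97.5]))
            result.h_ci = tuple(np.percentile(hs, [2.5, 97.5]))
            if plateau_mode == "free":
                result.plateau_ci = tuple(np.percentile(plats, [2.5, 97.5]))
    return result


def lowspeed_fraction_pelleted(ds: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD fraction of actin pelleted per condition (bundling assay).

    Per replicate the fraction pelleted is pellet/(pellet+supernatant) of
    the actin band; conditions (e.g. actin alone vs actin + binder) are
    aggregated separately. SD is the sample standard deviation (ddof=1;
    0 for a single replicate).
    """
    if "condition" not in ds.columns:
        raise ValueError("dataset needs a 'condition' column")
    validate_binding_dataset(ds, require_zero=False)
    if len(ds) == 0:
        raise ValueError("empty dataset")
    work = ds.copy()
    work["fraction_pelleted"] = work["pellet_intensity"] / (
        work["pellet_intensity"] + work["supernatant_intensity"]
    )
    out = (
        work.groupby("condition", sort=True)["fraction_pelleted"]
        .agg(
            mean_fraction_pelleted="mean",
            sd_fraction_pelleted=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    return out
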