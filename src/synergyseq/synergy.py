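"""Dose-matrix synergy analysis: Bliss independence and Loewe additivity.

Raw plate luminescence is first anchored to the plate controls,

    % reduced proliferation = 100 * (LO - EC0) / (EC100 - EC0),

with EC0 the mean negative control (DMSO, 0% reduction) and EC100 the mean
positive control (100% reduction).  The Bliss model treats the two drugs as
acting independently: expected fraction affected fab = fa + fb - fa*fb from
the monotherapy margins; the excess of the observed over the expected
surface (in percentage points) quantifies synergy, summarized as the mean
excess over the combination wells.  The Loewe model is dose-equivalence
based: at a well with doses (da, db) and observed effect E, the combination
index CI = da/DA(E) + db/DB(E), where DA, DB are the monotherapy doses
achieving E (CI < 1 synergy, 1 additivity, > 1 antagonism).  Monotherapy
margins are inverted through a four-parameter logistic (Hill) fit, with a
monotone isotonic fallback when the fit fails.  The isobologram plots
normalized dose pairs reaching a fixed effect level against the additivity
diagonal x + y = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.isotonic import IsotonicRegression

from .io_formats import DoseMatrix

__all__ = [
    "MonotherapyCurve",
    "SynergyResult",
    "percent_reduced_proliferation",
    "normalize_plate",
    "fit_monotherapy",
    "bliss_surface",
    "loewe_ci",
    "isobologram",
    "analyze_matrix",
    "synergy_vs_discordance",
]


def percent_reduced_proliferation(lo, ec0: float, ec100: float):
    """Control-anchored normalization of raw assay signal.

    100 * (LO - EC0) / (EC100 - EC0): 0% at the negative-control level, 100%
    at the positive-control level.  Values outside [0, 100] (assay noise)
    are retained.  Invariant under affine transforms applied to all inputs.
    """
    if ec100 == ec0:
        raise ValueError("EC100 equals EC0; normalization undefined")
    return 100.0 * (np.asarray(lo, dtype=float) - ec0) / (ec100 - ec0)


def normalize_plate(dm: DoseMatrix) -> DoseMatrix:
    """Convert a raw-luminescence plate to % reduced proliferation."""
    if dm.kind != "raw":
        raise ValueError("plate is already normalized")
    if dm.neg_controls is None or dm.pos_controls is None:
        raise ValueError("control wells missing; normalization impossible")
    ec0 = float(np.mean(dm.neg_controls))
    ec100 = float(np.mean(dm.pos_controls))
    effect = percent_reduced_proliferation(dm.values, ec0, ec100)
    out_of_range = int(((effect < 0) | (effect > 100)).sum())
    if out_of_range:
        warnings.warn(
            f"{out_of_range} wells outside [0, 100]% after normalization (assay noise)",
            UserWarning,
            stacklevel=2,
        )
    return DoseMatrix(
        drug_a=dm.drug_a,
        drug_b=dm.drug_b,
        doses_a=dm.doses_a,
        doses_b=dm.doses_b,
        values=effect,
        dose_unit=dm.dose_unit,
        kind="percent",
        neg_controls=dm.neg_controls,
        pos_controls=dm.pos_controls,
        replicates=dm.replicates,
    )


# ---------------------------------------------------------------------------
# monotherapy curves
# ---------------------------------------------------------------------------


def _hill(d, e0, emax, ec50, h):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d > 0, d**h / (ec50**h + d**h), 0.0)
    return e0 + (emax - e0) * frac


@dataclass
class MonotherapyCurve:
    """Monotone dose -> effect map with an inverse.

    ``method`` is "hill" (4PL least-squares fit: E0, Emax, EC50, slope h)
    when the fit converges with a positive slope, else "isotonic"
    (monotone interpolation of the observed margin).  The inverse is defined
    only on the achieved effect range and returns NaN outside it.
    """

    doses: np.ndarray
    effects: np.ndarray
    method: str = "hill"
    params: dict = field(default_factory=dict)
    _iso_d: np.ndarray | None = None
    _iso_e: np.ndarray | None = None

    def predict(self, d):
        if self.method == "hill":
            p = self.params
            return _hill(d, p["e0"], p["emax"], p["ec50"], p["h"])
        if self.method == "isotonic":
            return np.interp(np.asarray(d, dtype=float), self._iso_d, self._iso_e)
        return np.full_like(np.asarray(d, dtype=float), self.effects.mean())  # flat

    def inverse(self, effect):
        """Dose achieving ``effect``; NaN where the curve never reaches it."""
        e = np.asarray(effect, dtype=float)
        if self.method == "hill":
            p = self.params
            frac = (e - p["e0"]) / (p["emax"] - p["e0"])
            with np.errstate(divide="ignore", invalid="ignore"):
                d = p["ec50"] * (frac / (1.0 - frac)) ** (1.0 / p["h"])
            d = np.where((frac >= 0) & (frac < 1), d, np.nan)
            return d if d.ndim else float(d)
        if self.method == "isotonic":
            lo, hi = self._iso_e[0], self._iso_e[-1]
            ee, idx = np.unique(self._iso_e, return_index=True)
            d = np.interp(e, ee, self._iso_d[idx])
            d = np.where((e >= lo) & (e <= hi), d, np.nan)
            return d if d.ndim else float(d)
        return np.full_like(e, np.nan) if e.ndim else float("nan")

    @property
    def effect_range(self) -> tuple[float, float]:
        if self.method == "hill":
            return (self.params["e0"], self.params["emax"])
        if self.method == "isotonic":
            return (float(self._iso_e[0]), float(self._iso_e[-1]))
        return (float("nan"), float("nan"))


def fit_monotherapy(doses, effects) -> MonotherapyCurve:
    """Fit a monotone dose-response curve to one monotherapy margin.

    Tries a four-parameter logistic by least squares; falls back to isotonic
    interpolation (with a warning) when the fit fails, the slope is not
    positive, or the fit explains the data poorly.  Constant effects yield a
    flat curve with an undefined inverse.
    """
    d = np.asarray(doses, dtype=float)
    e = np.asarray(effects, dtype=float)
    if (d > 0).sum() < 3:
        raise ValueError("need at least 3 positive doses to fit a monotherapy curve")
    order = np.argsort(d)
    d, e = d[order], e[order]
    if np.allclose(e, e[0]):
        warnings.warn("constant monotherapy effects; flat fallback", UserWarning, stacklevel=2)
        return MonotherapyCurve(doses=d, effects=e, method="flat")
    pos = d[d > 0]
    p0 = (float(e.min()), float(e.max()), float(np.median(pos)), 1.0)
    bounds = (
        [-np.inf, -np.inf, pos.min() * 1e-3, 0.05],
        [np.inf, np.inf, pos.max() * 1e3, 20.0],
    )
    try:
        popt, _ = optimize.curve_fit(_hill, d, e, p0=p0, bounds=bounds, maxfev=20000)
        e0, emax, ec50, h = (float(v) for v in popt)
        resid = e - _hill(d, e0, emax, ec50, h)
        ss_res = float((resid**2).sum())
        ss_tot = float(((e - e.mean()) ** 2).sum())
        ok = emax > e0 and h > 0 and (ss_tot == 0 or 1 - ss_res / ss_tot > 0.8)
    except (RuntimeError, ValueError):
        ok = False
    if ok:
        return MonotherapyCurve(
            doses=d,
            effects=e,
            method="hill",
            params={"e0": e0, "emax": emax, "ec50": ec50, "h": h},
        )
    warnings.warn(
        "4PL fit failed or non-monotone; falling back to isotonic interpolation",
        UserWarning,
        stacklevel=2,
    )
    iso = IsotonicRegression(increasing=True).fit(d, e)
    fitted = iso.predict(d)
    return MonotherapyCurve(doses=d, effects=e, method="isotonic", _iso_d=d, _iso_e=fitted)


# ---------------------------------------------------------------------------
# Bliss
# ---------------------------------------------------------------------------


@dataclass
class SynergyResult:
    """Per-well surfaces and summaries for one dose matrix."""

    drug_a: str
    drug_b: str
    bliss_excess: pd.DataFrame | None = None  # percentage points; NaN on margins
    bliss_score: float | None = None  # mean excess over combination wells
    loewe_ci: pd.DataFrame | None = None  # combination index; NaN where undefined
    isobologram: pd.DataFrame | None = None  # columns x, y, effect_level
    curve_a: MonotherapyCurve | None = None
    curve_b: MonotherapyCurve | None = None
    notes: list = field(default_factory=list)


def _require_margins(dm: DoseMatrix) -> None:
    if dm.kind != "percent":
        raise ValueError("dose matrix must be normalized to % reduced proliferation first")
    if not dm.has_margins:
        raise ValueError("dose matrix lacks 0-dose monotherapy margins")


def bliss_surface(dm: DoseMatrix) -> SynergyResult:
    """Bliss-independence excess surface and mean score.

    Effects are clamped into [0, 1] fraction-affected before applying the
    independence model (it is undefined outside); the raw matrix is left
    untouched for audit.  Excess is defined only at wells with both doses
    positive; the score is the unweighted mean excess over those wells.
    """
    _require_margins(dm)
    f = np.clip(dm.values / 100.0, 0.0, 1.0)
    fa = f[:, 0][:, None]
    fb = f[0, :][None, :]
    expected = fa + fb - fa * fb
    excess = 100.0 * (f - expected)
    excess[0, :] = np.nan
    excess[:, 0] = np.nan
    combo = excess[1:, 1:]
    return SynergyResult(
        drug_a=dm.drug_a,
        drug_b=dm.drug_b,
        bliss_excess=pd.DataFrame(excess, index=dm.doses_a, columns=dm.doses_b),
        bliss_score=float(np.mean(combo)),
    )


# ---------------------------------------------------------------------------
# Loewe
# ---------------------------------------------------------------------------


def _margin_curves(dm: DoseMatrix) -> tuple[MonotherapyCurve, MonotherapyCurve]:
    curve_a = fit_monotherapy(dm.doses_a, dm.values[:, 0])
    curve_b = fit_monotherapy(dm.doses_b, dm.values[0, :])
    return curve_a, curve_b


def loewe_ci(
    dm: DoseMatrix,
    curves: tuple[MonotherapyCurve, MonotherapyCurve] | None = None,
) -> tuple[pd.DataFrame, MonotherapyCurve, MonotherapyCurve]:
    """Loewe combination index at every treated well.

    At well (da, db) with observed effect E, CI = da/DA(E) + db/DB(E); a
    zero dose contributes nothing.  Wells whose effect lies outside a needed
    monotherapy curve's achievable range get NaN (undefined, logged).
    """
    _require_margins(dm)
    curve_a, curve_b = curves if curves is not None else _margin_curves(dm)
    ci = np.full_like(dm.values, np.nan)
    n_undef = 0
    for i, da in enumerate(dm.doses_a):
        for j, db in enumerate(dm.doses_b):
            if da == 0 and db == 0:
                continue
            e_obs = dm.values[i, j]
            total = 0.0
            ok = True
            for dose, curve in ((da, curve_a), (db, curve_b)):
                if dose <= 0:
                    continue
                d_needed = curve.inverse(e_obs)
                if not np.isfinite(d_needed) or d_needed <= 0:
                    ok = False
                    break
                total += dose / d_needed
            if ok:
                ci[i, j] = total
            else:
                n_undef += 1
    if n_undef:
        warnings.warn(
            f"Loewe CI undefined at {n_undef} wells (effect outside monotherapy range)",
            UserWarning,
            stacklevel=2,
        )
    return (
        pd.DataFrame(ci, index=dm.doses_a, columns=dm.doses_b),
        curve_a,
        curve_b,
    )


def isobologram(
    dm: DoseMatrix,
    effect_level: float = 50.0,
    curves: tuple[MonotherapyCurve, MonotherapyCurve] | None = None,
) -> pd.DataFrame:
    """Normalized dose pairs reaching ``effect_level``, for the isobologram.

    For each fixed dose of one drug, the crossing of the effect surface with
    the level is located by linear interpolation along the other drug's dose
    axis; the point (da/DA, db/DB) is emitted, with DA, DB the monotherapy
    doses achieving the level.  Points below the diagonal x + y = 1 indicate
    synergy, above it antagonism.
    """
    _require_margins(dm)
    curve_a, curve_b = curves if curves is not None else _margin_curves(dm)
    da_ref = curve_a.inverse(effect_level)
    db_ref = curve_b.inverse(effect_level)
    if not (np.isfinite(da_ref) and da_ref > 0 and np.isfinite(db_ref) and db_ref > 0):
        raise ValueError(
            f"effect level {effect_level}% not reachable by both monotherapies "
            f"(achieved ranges: {dm.drug_a} {curve_a.effect_range}, "
            f"{dm.drug_b} {curve_b.effect_range})"
        )

    def crossings(doses_fixed, doses_var, grid, axis_is_a: bool):
        pts = []
        for jf in range(1, len(doses_fixed)):
            profile = grid[:, jf] if axis_is_a else grid[jf, :]
            for k in range(1, len(doses_var)):
                lo, hi = profile[k - 1], profile[k]
                if (lo - effect_level) * (hi - effect_level) <= 0 and lo != hi:
                    frac = (effect_level - lo) / (hi - lo)
                    d_var = doses_var[k - 1] + frac * (doses_var[k] - doses_var[k - 1])
                    if axis_is_a:
                        pts.append((d_var / da_ref, doses_fixed[jf] / db_ref))
                    else:
                        pts.append((doses_fixed[jf] / da_ref, d_var / db_ref))
                    break
        return pts

    points = crossings(dm.doses_b, dm.doses_a, dm.values, axis_is_a=True)
    points += crossings(dm.doses_a, dm.doses_b, dm.values, axis_is_a=False)
    df = pd.DataFrame(points, columns=["x", "y"]).drop_duplicates()
    df["effect_level"] = effect_level
    return df.reset_index(drop=True)


def analyze_matrix(
    dm: DoseMatrix,
    effect_level: float = 50.0,
    do_bliss: bool = True,
    do_loewe: bool = True,
) -> SynergyResult:
    """Run the full synergy evaluation of one normalized dose matrix."""
    result = SynergyResult(drug_a=dm.drug_a, drug_b=dm.drug_b)
    if do_bliss:
        b = bliss_surface(dm)
        result.bliss_excess, result.bliss_score = b.bliss_excess, b.bliss_score
    if do_loewe:
        ci, curve_a, curve_b = loewe_ci(dm)
        result.loewe_ci = ci
        result.curve_a, result.curve_b = curve_a, curve_b
        try:
            result.isobologram = isobologram(dm, effect_level, curves=(curve_a, curve_b))
        except ValueError as exc:
            result.notes.append(str(exc))
    return result


def synergy_vs_discordance(synergy_values, discordance_values) -> dict:
    """Association between per-cell-line synergy and discordance.

    Returns Pearson r and Spearman rho with n.  Expected signs: Bliss score
    correlates positively with discordance, Loewe CI negatively.
    """
    x = np.asarray(synergy_values, dtype=float)
    y = np.asarray(discordance_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D inputs required")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pearson.statistic),
        "spearman_rho": float(spearman.statistic),
        "n": int(len(x)),
    }
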