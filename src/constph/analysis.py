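"""Titration curves, Hill fits with jackknife errors, and pKa benchmarking.

Replicate occupancy series are aggregated (after discarding an equilibration
fraction) into per-pH mean curves with standard errors of the mean.  Site
pKa values come from least-squares fits of the Hill equation

    f(pH) = 1 / (1 + 10^{n (pH - pKa)})

to the mean protonation fraction; errors are estimated by leave-one-out
(jackknife) refits over the replicates.  The benchmarking layer computes
RMSE / MAE / ME (bias, predicted - experimental) / maximum deviation against
experimental pKa values, globally and per residue type, together with a null
model that predicts every residue at its residue-type reference
(pentapeptide) pKa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class TitrationCurve:
    """Per-pH protonation fractions across replicates."""

    ph_values: np.ndarray
    replicate_fractions: np.ndarray   # (n_replicates, n_ph)
    label: str | None = None
    window: str | None = None

    def __post_init__(self):
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.replicate_fractions = np.atleast_2d(
            np.asarray(self.replicate_fractions, dtype=float))
        if self.replicate_fractions.shape[1] != len(self.ph_values):
            raise ValueError("replicate matrix does not match pH grid")
        if np.any((self.replicate_fractions < -1e-9)
                  | (self.replicate_fractions > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_replicates(self) -> int:
        return self.replicate_fractions.shape[0]

    @property
    def mean_fraction(self) -> np.ndarray:
        return self.replicate_fractions.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        r = self.n_replicates
        if r < 2:
            return np.zeros(len(self.ph_values))
        return self.replicate_fractions.std(axis=0, ddof=1) / math.sqrt(r)


@dataclass
class HillFit:
    pka: float
    hill_n: float
    pka_error: float | None = None
    converged: bool = True
    window: str | None = None

    def __post_init__(self):
        if self.converged and not (math.isfinite(self.pka)
                                   and self.hill_n > 0):
            raise ValueError("converged fit requires finite pKa and n > 0")


def aggregate(replicate_series: list[dict[float, np.ndarray]],
              burn_in_fraction: float = 0.2,
              window: tuple[int, int] | None = None,
              label: str | None = None):
    """Collapse per-replicate occupancy time series into titration curve(s).

    ``replicate_series`` is one dict per replicate mapping pH to a 1-D series
    of instantaneous protonation occupancies.  The first ``burn_in_fraction``
    of every series is discarded (default 0.2, i.e. the first fifth of the
    run).  With ``window=(width, step)`` (in samples, applied after burn-in
    removal is skipped -- windows slide over the *full* series), a list of
    curves is returned, one per window.
    """
    if not replicate_series:
        raise ValueError("need at least one replicate")
    ph_values = sorted(replicate_series[0].keys())
    for rep in replicate_series:
        if sorted(rep.keys()) != ph_values:
            raise ValueError("replicates have different pH grids")

    def mean_segment(series, lo, hi):
        seg = np.asarray(series, dtype=float)[lo:hi]
        if len(seg) == 0:
            raise ValueError("empty post-burn-in segment")
        return float(seg.mean())

    if window is None:
        rows = []
        for rep in replicate_series:
            row = []
            for ph in ph_values:
                series = np.asarray(rep[ph], dtype=float)
                lo = int(round(burn_in_fraction * len(series)))
                row.append(mean_segment(series, lo, len(series)))
            rows.append(row)
        return TitrationCurve(np.array(ph_values), np.array(rows), label=label)

    width, step = window
    length = min(len(np.asarray(rep[ph])) for rep in replicate_series
                 for ph in ph_values)
    curves = []
    for start in range(0, length - width + 1, step):
        rows = [[mean_segment(rep[ph], start, start + width)
                 for ph in ph_values] for rep in replicate_series]
        curves.append(TitrationCurve(np.array(ph_values), np.array(rows),
                                     label=label,
                                     window=f"{start}-{start + width}"))
    return curves


def _hill(ph, pka, n):
    return 1.0 / (1.0 + 10.0 ** (n * (ph - pka)))


def fit_hill(curve: TitrationCurve, fractions: np.ndarray | None = None) -> HillFit:
    """Least-squares Hill fit of the mean titration curve.

    Marked unconverged when fewer than 3 points lie strictly inside (0, 1),
    on optimizer failure, or when the fitted pKa falls outside
    [pH_min - 2, pH_max + 2] (mirroring ">12"-style extrapolated values).
    """
    ph = curve.ph_values
    f = curve.mean_fraction if fractions is None else np.asarray(fractions)
    interior = (f > 0.0) & (f < 1.0)
    if interior.sum() < 3:
        return HillFit(math.nan, math.nan, converged=False,
                       window=curve.window)
    guess_pka = float(ph[np.argmin(np.abs(f - 0.5))])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_hill, ph, f, p0=[guess_pka, 1.0],
                                bounds=([ph.min() - 10, 1e-6],
                                        [ph.max() + 10, 5.0]),
                                maxfev=10000)
    except (RuntimeError, ValueError):
        return HillFit(math.nan, math.nan, converged=False,
                       window=curve.window)
    pka, n = float(popt[0]), float(popt[1])
    if not (ph.min() - 2.0 <= pka <= ph.max() + 2.0):
        return HillFit(pka, n, converged=False, window=curve.window)
    return HillFit(pka, n, window=curve.window)


def jackknife_error(values: np.ndarray) -> float:
    """Jackknife standard error from the leave-one-out estimates."""
    v = np.asarray(values, dtype=float)
    m = len(v)
    return float(math.sqrt((m - 1) / m * np.sum((v - v.mean()) ** 2)))


@dataclass
class JackknifeResult:
    error: float | None
    pka_values: list[float]
    dropped: list[int] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.error is not None


def jackknife_pka(curve: TitrationCurve) -> JackknifeResult:
    """Leave-one-replicate-out Hill refits; error from the jackknife formula.

    Combinations whose Hill fit fails to converge are dropped and reported;
    if all fail the error is undefined (mirrors omitted error bars).
    """
    r = curve.n_replicates
    if r < 2:
        raise ValueError("jackknife needs at least 2 replicates")
    pkas, dropped = [], []
    for k in range(r):
        keep = [i for i in range(r) if i != k]
        loo = curve.replicate_fractions[keep].mean(axis=0)
        fit = fit_hill(curve, fractions=loo)
        if fit.converged:
            pkas.append(fit.pka)
        else:
            dropped.append(k)
    if not pkas:
        return JackknifeResult(None, [], dropped)
    return JackknifeResult(jackknife_error(np.array(pkas)), pkas, dropped)


def fit_site(curve: TitrationCurve) -> HillFit:
    """Hill fit of the mean curve with jackknife error when replicates allow."""
    fit = fit_hill(curve)
    if fit.converged and curve.n_replicates >= 2:
        jk = jackknife_pka(curve)
        fit.pka_error = jk.error
    return fit


# --------------------------------------------------------------------------
# total charge curves and isoelectric point
# --------------------------------------------------------------------------

def total_charge_curve(site_curves: dict[int, TitrationCurve],
                       formal_charges: dict[int, tuple[float, float]],
                       background_charge: float = 0.0):
    """Average total charge per pH.

    ``formal_charges[sid] = (z_protonated, z_deprotonated)``; the mean charge
    of a site at a pH with protonation fraction f is z_p f + z_d (1 - f).
    """
    if not site_curves:
        ph = np.array([])
    else:
        first = next(iter(site_curves.values()))
        ph = first.ph_values
    charge = np.full(len(ph), float(background_charge))
    for sid, curve in site_curves.items():
        if not np.array_equal(curve.ph_values, ph):
            raise ValueError("site curves have inconsistent pH grids")
        zp, zd = formal_charges[sid]
        f = curve.mean_fraction
        charge = charge + zp * f + zd * (1.0 - f)
    return ph, charge


def isoelectric_point(ph_values: np.ndarray, charge: np.ndarray) -> float:
    """pH of zero mean charge, by linear interpolation of the charge curve.

    With several sign changes the smallest root is returned with a warning;
    a one-signed curve has no pI and raises.
    """
    ph = np.asarray(ph_values, dtype=float)
    q = np.asarray(charge, dtype=float)
    roots = []
    for i in range(len(ph) - 1):
        a, b = q[i], q[i + 1]
        if a == 0.0:
            roots.append(float(ph[i]))
        elif a * b < 0:
            roots.append(float(ph[i] - a * (ph[i + 1] - ph[i]) / (b - a)))
    if q[-1] == 0.0:
        roots.append(float(ph[-1]))
    if not roots:
        raise ValueError("charge curve does not change sign: pI undefined")
    if len(roots) > 1:
        warnings.warn(f"multiple charge-curve roots {roots}; returning the "
                      f"smallest", stacklevel=2)
    return roots[0]


def contact_fraction(distances: np.ndarray, cutoff: float = 0.4) -> float:
    """Percentage of frames with minimum side-chain distance <= cutoff (nm)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    return 100.0 * float(np.mean(d <= cutoff))


# --------------------------------------------------------------------------
# benchmarking against experimental pKa values
# --------------------------------------------------------------------------

def _metrics(errors: np.ndarray) -> dict:
    return {
        "rmse": float(np.sqrt(np.mean(errors ** 2))),
        "mae": float(np.mean(np.abs(errors))),
        "me": float(np.mean(errors)),
        "max_dev": float(np.max(np.abs(errors))),
        "n": int(len(errors)),
    }


@dataclass
class BenchmarkReport:
    rmse: float
    mae: float
    me: float
    max_dev: float
    n: int
    per_type: dict[str, dict]
    null: dict | None
    excluded: list[tuple[str, str]]

    def __post_init__(self):
        # internal-consistency invariants of the error metrics
        assert self.mae <= self.rmse + 1e-12
        assert abs(self.me) <= self.mae + 1e-12
        assert self.max_dev >= self.rmse - 1e-12


def benchmark(predicted: dict[str, float], experimental: dict[str, float],
              residue_types: dict[str, str],
              references: dict[str, float] | None = None,
              exclude_types: tuple[str, ...] = ("TYR",),
              unconverged: set[str] = frozenset()) -> BenchmarkReport:
    """Error metrics of pKa predictions against experimental values.

    Metrics run over the key intersection of ``predicted`` and
    ``experimental``; residues of an excluded type (tyrosines by default,
    whose fitted pKa values fall outside the simulated pH range) or flagged
    unconverged are dropped and listed.  With ``references`` (residue-type
    reference pKa values) the null model -- predict every residue at its
    type's reference -- is evaluated on the same residue set.
    """
    excluded: list[tuple[str, str]] = []
    keys = []
    for key in sorted(set(predicted) & set(experimental)):
        rtype = residue_types.get(key, "").upper()
        if rtype in tuple(t.upper() for t in exclude_types):
            excluded.append((key, f"excluded residue type {rtype}"))
        elif key in unconverged:
            excluded.append((key, "Hill fit not converged"))
        else:
            keys.append(key)
    if not keys:
        raise ValueError("no residues left to benchmark")

    errors = np.array([predicted[k] - experimental[k] for k in keys])
    glob = _metrics(errors)

    per_type: dict[str, dict] = {}
    for rtype in sorted({residue_types.get(k, "?").upper() for k in keys}):
        tkeys = [k for k in keys if residue_types.get(k, "?").upper() == rtype]
        terr = np.array([predicted[k] - experimental[k] for k in tkeys])
        per_type[rtype] = _metrics(terr)

    null = None
    if references is not None:
        refs = {t.upper(): v for t, v in references.items()}
        nerr = np.array([refs[residue_types[k].upper()] - experimental[k]
                         for k in keys])
        null = _metrics(nerr)

    return BenchmarkReport(glob["rmse"], glob["mae"], glob["me"],
                           glob["max_dev"], glob["n"], per_type, null,
                           excluded)


def rmse_between(pred_a: dict[str, float], pred_b: dict[str, float]) -> float:
    """RMSE between two prediction sets over their shared residues
    (the force-field-vs-force-field comparison mode)."""
    keys = sorted(set(pred_a) & set(pred_b))
    if not keys:
        raise ValueError("no shared residues")
    d = np.array([pred_a[k] - pred_b[k] for k in keys])
    return float(np.sqrt(np.mean(d ** 2)))
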