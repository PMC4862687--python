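"""Receptor-activation assay quantification and qPCR relative expression.

Aequorin luminescence responses are normalized to the total calcium
response (peptide + detergent lysis), expressed as percent of the
concentration series maximum, and fitted with a four-parameter logistic
(variable-slope sigmoid) on log10 concentration to estimate the EC50.
qPCR quantification follows the ddCt convention with the error range
computed from ddCt +/- SEM, SEM taken over the test-condition dCt
replicates only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class DoseResponseSeries:
    ligand: str
    receptor: str
    points: list[tuple[float, float]]  # (concentration M, normalized response)
    replicate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c, r in self.points:
            if c <= 0:
                raise ValueError("concentrations must be positive")
        if not self.replicate_ids:
            self.replicate_ids = ["r1"] * len(self.points)

    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    def responses(self) -> np.ndarray:
        return np.array([r for _, r in self.points])


@dataclass
class FourPLFit:
    ec50: float
    hill: float
    top: float
    bottom: float
    converged: bool
    rss: float
    unreliable: bool = False
    message: str = ""


def normalize_response(peptide_lum: float, triton_lum: float) -> float:
    """Fraction of the total calcium response attributable to the peptide."""
    if peptide_lum < 0 or triton_lum < 0:
        raise ValueError("luminescence readings must be non-negative")
    total = peptide_lum + triton_lum
    if total == 0:
        raise ValueError("total luminescence is zero")
    return peptide_lum / total


def percent_of_max(series: DoseResponseSeries) -> DoseResponseSeries:
    """Rescale responses to percent of the series maximum (max maps to 100)."""
    if not series.points:
        raise ValueError("empty series")
    peak = max(r for _, r in series.points)
    if peak <= 0:
        raise ValueError("series maximum must be positive")
    return DoseResponseSeries(
        ligand=series.ligand,
        receptor=series.receptor,
        points=[(c, 100.0 * (r / peak)) for c, r in series.points],
        replicate_ids=list(series.replicate_ids),
    )


def _four_pl(logx: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float):
    expo = np.clip(hill * (log_ec50 - logx), -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** expo)


def fit_4pl(series: DoseResponseSeries, fit_on_means: bool = False) -> FourPLFit:
    """Least-squares four-parameter logistic fit on log10 concentration.

    Initialization takes bottom/top from the data extremes, the EC50 start
    from the concentration nearest the half-range response, and tries
    several Hill-slope starts (signs and magnitudes), keeping the best-RSS
    solution.  All replicate points are fitted jointly unless
    ``fit_on_means`` collapses replicates to concentration means.
    Failure to converge is reported in the flag, never raised; a flat
    series yields an unreliable EC50 flag.
    """
    conc = series.concentrations()
    resp = series.responses()
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if fit_on_means:
        df = pd.DataFrame({"c": conc, "r": resp}).groupby("c").mean().reset_index()
        conc, resp = df["c"].to_numpy(), df["r"].to_numpy()
    logx = np.log10(conc)

    lo, hi = float(resp.min()), float(resp.max())
    span = hi - lo
    if span <= 1e-12 * max(abs(hi), 1.0):
        return FourPLFit(
            ec50=float(10 ** logx.mean()), hill=0.0, top=hi, bottom=lo,
            converged=False, rss=0.0, unreliable=True, message="flat series",
        )
    half = lo + span / 2.0
    ec50_start = conc[int(np.argmin(np.abs(resp - half)))]

    best = None
    for hill0 in (1.0, -1.0, 3.0):
        p0 = [lo, hi, math.log10(ec50_start), hill0]
        try:
            popt, _ = curve_fit(
                _four_pl, logx, resp, p0=p0, maxfev=20000,
                bounds=(
                    [-np.inf, -np.inf, logx.min() - 6, -50],
                    [np.inf, 1.5 * hi if hi > 0 else np.inf, logx.max() + 6, 50],
                ),
            )
        except RuntimeError:
            continue
        rss = float(((resp - _four_pl(logx, *popt)) ** 2).sum())
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return FourPLFit(
            ec50=float("nan"), hill=float("nan"), top=hi, bottom=lo,
            converged=False, rss=float("nan"), unreliable=True,
            message="no start converged",
        )
    (bottom, top, log_ec50, hill), rss = best
    unreliable = abs(hill) < 0.05 or not (logx.min() - 3 < log_ec50 < logx.max() + 3)
    if bottom > top:
        bottom, top, hill = top, bottom, -hill
    return FourPLFit(
        ec50=float(10.0 ** log_ec50), hill=float(hill), top=float(top),
        bottom=float(bottom), converged=True, rss=rss, unreliable=unreliable,
    )


def bootstrap_ec50_ci(
    series: DoseResponseSeries,
    n_resamples: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Nonparametric bootstrap confidence interval for the EC50.

    Resamples replicate points within each concentration, refits, and
    returns the percentile interval of the fitted EC50s.
    """
    rng = np.random.RandomState(seed)
    conc = series.concentrations()
    resp = series.responses()
    estimates = []
    by_conc: dict[float, np.ndarray] = {
        c: np.flatnonzero(conc == c) for c in np.unique(conc)
    }
    for _ in range(n_resamples):
        idx = np.concatenate(
            [rng.choice(ix, size=len(ix), replace=True) for ix in by_conc.values()]
        )
        boot = DoseResponseSeries(
            series.ligand, series.receptor,
            [(float(conc[i]), float(resp[i])) for i in idx],
        )
        fit = fit_4pl(boot)
        if fit.converged and not fit.unreliable:
            estimates.append(fit.ec50)
    if not estimates:
        return float("nan"), float("nan")
    a = (1.0 - level) / 2.0
    return tuple(np.quantile(estimates, [a, 1.0 - a]))


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class CtTable:
    """Per-(sample, gene) qPCR cycle thresholds with condition labels."""

    ct: pd.DataFrame  # samples x genes
    conditions: dict[str, str]  # sample -> condition label
    reference_gene: str

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.columns:
            raise ValueError(f"reference gene {self.reference_gene!r} missing")
        if self.ct[self.reference_gene].isna().any():
            raise ValueError("reference gene Ct missing for some sample")


@dataclass
class RelativeQuantity:
    rq: float
    ddct: float
    sem: float
    range_low: float
    range_high: float


def delta_delta_ct(
    table: CtTable, gene: str, test_condition: str, reference_condition: str
) -> RelativeQuantity:
    """ddCt relative quantification with the asymmetric SEM error range.

    dCt per sample = Ct(gene) - Ct(reference gene); ddCt = mean dCt(test)
    - mean dCt(reference condition); RQ = 2^-ddCt.  The error range is
    [2^-(ddCt+SEM), 2^-(ddCt-SEM)] with SEM over the test-condition dCt
    replicates only.
    """
    if gene not in table.ct.columns:
        raise ValueError(f"gene {gene!r} not in Ct table")
    dct = table.ct[gene] - table.ct[table.reference_gene]
    test = dct[[s for s in dct.index if table.conditions[s] == test_condition]]
    ref = dct[[s for s in dct.index if table.conditions[s] == reference_condition]]
    if len(test) == 0 or len(ref) == 0:
        raise ValueError("both conditions need at least one replicate")
    ddct = float(test.mean() - ref.mean())
    sem = float(test.std(ddof=1) / math.sqrt(len(test))) if len(test) >= 2 else 0.0
    rq = 2.0 ** (-ddct)
    return RelativeQuantity(
        rq=rq,
        ddct=ddct,
        sem=sem,
        range_low=2.0 ** (-(ddct + sem)),
        range_high=2.0 ** (-(ddct - sem)),
    )
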