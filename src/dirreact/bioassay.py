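"""Dose–response summarization and model-vs-experiment association.

Covers the experimental side of the directional-reactivity workflow for
AhR-mediated potency: normalizing reporter-assay luminescence to the
benzo[a]pyrene maximum (%BaP_max), estimating EC50 by a four-parameter
log-logistic fit — optionally constrained to share slope and asymptotes
with a reference compound (the equal-efficacy / parallelism assumption) —
and correlating predicted reactivity scores with observed potencies.

Also ships a verbatim transcription of the published per-compound tables
for the 12 chrysene homologues (electronic-structure descriptors, DRF
scores, and bioassay/QSAR/docking potency columns).  EC50 columns are kept
in the printed unit of 10⁻¹ μM with a conversion accessor.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseCurve",
    "PotencyEstimate",
    "AssociationResult",
    "normalize_to_bapmax",
    "fit_ec50",
    "association",
    "load_reference_tables",
    "ec50_h4iie_um",
]

_REFERENCE_SHA256 = (
    "d71b1eb6476a1fa184ad5048a262572368054b7a77a0495413b503426b858801"
)


@dataclass(frozen=True)
class DoseResponseCurve:
    """One compound's doses (μM) and %BaP_max responses.

    ``doses`` and ``responses`` are parallel arrays; replicates appear as
    repeated dose values.  Doses must be strictly positive and sorted
    ascending; at least 4 distinct doses are required for fitting.
    """

    compound: str
    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.shape != r.shape or d.ndim != 1:
            raise ValueError("doses and responses must be parallel 1-D arrays")
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(d) < 0):
            raise ValueError("doses must be sorted ascending")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "responses", r)

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.doses).size)


@dataclass(frozen=True)
class PotencyEstimate:
    """EC50 (μM) with fit metadata from the log-logistic model."""

    ec50: float
    log_ec50_se: float
    top: float
    bottom: float
    hill: float
    method: str

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise ValueError("EC50 must be positive")


@dataclass(frozen=True)
class AssociationResult:
    method: str
    statistic: float
    p_value: float
    n: int
    transform: str


def normalize_to_bapmax(
    raw_luminescence: Sequence[float] | np.ndarray, reference_max: float
) -> np.ndarray:
    """Express raw luminescence as percent of the reference-agonist maximum."""
    if not reference_max > 0:
        raise ValueError("reference maximum must be positive")
    return 100.0 * np.asarray(raw_luminescence, dtype=float) / reference_max


def _loglogistic(logx: np.ndarray, bottom: float, top: float, hill: float,
                 log_ec50: float) -> np.ndarray:
    # increasing 4-parameter log-logistic on log10 dose
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logx)))


def fit_ec50(
    curve: DoseResponseCurve,
    reference: DoseResponseCurve | None = None,
) -> PotencyEstimate:
    """Four-parameter log-logistic EC50 fit, optionally parallel to a reference.

    Without a reference, bottom/top/hill/EC50 are all free.  With one, the
    reference curve is fit first and its bottom, top and Hill slope are
    imposed on the target (equal efficacy and parallelism); only the curve
    midpoint shifts.  EC50 is returned in μM with the standard error of
    log10 EC50 from the fit covariance.
    """
    if curve.n_distinct_doses < 4:
        raise ValueError("need at least 4 distinct doses to fit an EC50")
    if float(np.ptp(curve.responses)) == 0.0:
        raise ValueError("responses show no variation; EC50 undefined")

    logx = np.log10(curve.doses)
    y = curve.responses

    def _p0(c: DoseResponseCurve) -> list[float]:
        lo, hi = float(np.min(c.responses)), float(np.max(c.responses))
        mid = 0.5 * (lo + hi)
        lx = np.log10(c.doses)
        guess = float(lx[np.argmin(np.abs(c.responses - mid))])
        return [lo, hi, 1.0, guess]

    try:
        if reference is None:
            popt, pcov = optimize.curve_fit(
                _loglogistic, logx, y, p0=_p0(curve), maxfev=20000
            )
            bottom, top, hill, log_ec50 = popt
            se = float(np.sqrt(pcov[3, 3]))
            method = "4PL log-logistic"
        else:
            ref_fit = fit_ec50(reference)
            bottom, top, hill = ref_fit.bottom, ref_fit.top, ref_fit.hill

            def shifted(lx, log_ec50):
                return _loglogistic(lx, bottom, top, hill, log_ec50)

            popt, pcov = optimize.curve_fit(
                shifted, logx, y, p0=[_p0(curve)[3]], maxfev=20000
            )
            log_ec50 = popt[0]
            se = float(np.sqrt(pcov[0, 0]))
            method = "4PL log-logistic, shared slope/asymptotes"
    except RuntimeError as exc:
        raise RuntimeError(
            f"EC50 fit failed to converge for {curve.compound!r}: {exc}"
        ) from exc

    ec50 = float(10.0 ** log_ec50)
    if not np.isfinite(ec50) or ec50 <= 0:
        raise RuntimeError(
            f"EC50 fit for {curve.compound!r} produced a non-physical value"
        )
    return PotencyEstimate(
        ec50=ec50,
        log_ec50_se=se,
        top=float(top),
        bottom=float(bottom),
        hill=float(hill),
        method=method,
    )


_TRANSFORMS = {
    "identity": lambda v: v,
    "reciprocal": lambda v: 1.0 / v,
    "log10": np.log10,
}


def association(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    method: str = "pearson_r2",
    transform: str = "identity",
) -> AssociationResult:
    """Correlation between a predictor and observed potency.

    ``pearson_r2`` reports the squared Pearson correlation after applying
    ``transform`` to both variables; ``spearman`` reports the rank
    correlation with mid-ranks for ties.  p-values are two-sided.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be parallel 1-D arrays")
    if xv.size < 3:
        raise ValueError("need at least 3 points")
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    xv = _TRANSFORMS[transform](xv)
    yv = _TRANSFORMS[transform](yv)
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
        raise ValueError("non-finite values after transform")
    if float(np.ptp(xv)) == 0.0 or float(np.ptp(yv)) == 0.0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson_r2":
        res = stats.pearsonr(xv, yv)
        stat = float(res.statistic) ** 2
    elif method == "spearman":
        res = stats.spearmanr(xv, yv)
        stat = float(res.statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AssociationResult(
        method=method,
        statistic=stat,
        p_value=float(res.pvalue),
        n=int(xv.size),
        transform=transform,
    )


def load_reference_tables() -> pd.DataFrame:
    """Packaged transcription of the 12-compound reference tables.

    Columns: HOMO/LUMO/gap (eV), dipole magnitude (printed model units),
    maximal Fukui value and its carbon label(s), orientation class (F/P/B),
    DRF score, bioassay and QSAR EC50s (printed unit: 10⁻¹ μM), docking
    free energy (kcal/mol) and binding distances (Å).  The file's checksum
    is verified on load.
    """
    ref = resources.files("dirreact.data").joinpath("reference_tables.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise RuntimeError(
            "packaged reference table is corrupted "
            f"(sha256 {digest} != {_REFERENCE_SHA256})"
        )
    df = pd.read_csv(ref.open("r"), index_col="compound")
    if len(df) != 12:
        raise RuntimeError("reference table must list exactly 12 compounds")
    return df


def ec50_h4iie_um(table: pd.DataFrame) -> pd.Series:
    """Bioassay EC50 column converted from the printed 10⁻¹ μM unit to μM."""
    return table["ec50_h4iie_deci_um"] * 0.1
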