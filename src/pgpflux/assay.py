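"""Derived assay readouts: referencing, transport ratios, vesicle uptake.

Three post-processing steps turn raw measurements into the numbers a
transport study reports:

* double referencing of sensorgrams (sample minus reference channel
  minus blank injection);
* the ATP / no-nucleotide amplitude ratio, a dimensionless proxy for a
  substrate's relative Pgp transport rate;
* vesicle-assay absorbance time courses converted to substrate
  concentration through a standard curve and summarised as a transport
  efficiency, the percentage of substrate removed from the external
  buffer::

      efficiency(%) = (C_initial - C_sample) / C_initial * 100
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .synth import SensorgramSet
from .transport import end_of_association_amplitude

__all__ = [
    "TransportRatio",
    "StandardCurve",
    "double_reference",
    "transport_ratio",
    "transport_efficiency",
    "fit_standard_curve",
    "absorbance_to_concentration",
    "correct_sampling_dilution",
    "vesicle_assay_efficiency",
]


@dataclass(frozen=True)
class TransportRatio:
    """ATP / no-nucleotide amplitude ratio for one substrate."""

    drug_label: str
    ratio: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.sd < 0 or self.n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")


def double_reference(sample: np.ndarray, reference_channel: np.ndarray,
                     blank_injection: np.ndarray,
                     times: Sequence[np.ndarray] | None = None) -> np.ndarray:
    """Pointwise ``sample - reference - blank``.

    When ``times`` (one grid per trace) is given, the grids must agree
    exactly — there is deliberately no silent interpolation.
    """
    s = np.asarray(sample, float)
    r = np.asarray(reference_channel, float)
    b = np.asarray(blank_injection, float)
    if s.shape != r.shape or s.shape != b.shape:
        raise ValueError("traces must have identical shapes")
    if times is not None:
        ts, tr, tb = (np.asarray(t, float) for t in times)
        if ts.shape != tr.shape or ts.shape != tb.shape or \
                not (np.array_equal(ts, tr) and np.array_equal(ts, tb)):
            raise ValueError("time grids are misaligned; resample explicitly first")
    return s - r - b


def transport_ratio(atp_set: SensorgramSet, apo_set: SensorgramSet,
                    method: Literal["mean-of-ratios", "ratio-of-means"] = "mean-of-ratios",
                    drug_label: str | None = None) -> TransportRatio:
    """ATP vs no-nucleotide amplitude ratio across a concentration series.

    End-of-association amplitudes are computed per concentration in each
    arm; ``"mean-of-ratios"`` (default) averages the per-concentration
    amplitude ratios and reports their spread, ``"ratio-of-means"``
    ratios the mean amplitudes.  Concentrations whose no-nucleotide
    amplitude is zero or negative are excluded with a warning.
    """
    if atp_set.concentrations_um.shape != apo_set.concentrations_um.shape or \
            not np.allclose(atp_set.concentrations_um, apo_set.concentrations_um):
        raise ValueError("the two sets must share a concentration series")
    amp_atp = np.array([end_of_association_amplitude(atp_set.times, tr, atp_set.phases)
                        for tr in atp_set.traces])
    amp_apo = np.array([end_of_association_amplitude(apo_set.times, tr, apo_set.phases)
                        for tr in apo_set.traces])
    ok = amp_apo > 0
    if not np.all(ok):
        warnings.warn(f"excluding {np.count_nonzero(~ok)} concentration(s) with "
                      "non-positive reference amplitude")
    if not np.any(ok):
        raise ValueError("transport ratio undefined: no usable concentrations")
    if method == "mean-of-ratios":
        ratios = amp_atp[ok] / amp_apo[ok]
        ratio = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    elif method == "ratio-of-means":
        ratio = float(np.mean(amp_atp[ok]) / np.mean(amp_apo[ok]))
        sd = 0.0
        if np.count_nonzero(ok) > 1:
            # delta-method propagation of across-concentration spread
            ma, mb = np.mean(amp_atp[ok]), np.mean(amp_apo[ok])
            va = np.var(amp_atp[ok], ddof=1) / np.count_nonzero(ok)
            vb = np.var(amp_apo[ok], ddof=1) / np.count_nonzero(ok)
            sd = float(abs(ratio) * math.sqrt(va / ma**2 + vb / mb**2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TransportRatio(drug_label=drug_label or atp_set.condition,
                          ratio=ratio, sd=sd, n=int(np.count_nonzero(ok)))


def transport_efficiency(initial_conc: float, sample_conc: float) -> float:
    """Percent of substrate moved out of the external buffer.

    Negative values (sample above initial, i.e. net release) are allowed
    but flagged with a warning.
    """
    if initial_conc <= 0:
        raise ZeroDivisionError("initial concentration must be positive")
    if sample_conc < 0:
        raise ValueError("sample concentration must be >= 0")
    eff = (initial_conc - sample_conc) / initial_conc * 100.0
    if eff < 0:
        warnings.warn(f"negative transport efficiency ({eff:.3g}%): "
                      "release exceeds baseline")
    return eff


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance-vs-concentration calibration."""

    slope: float      # AU per μM
    intercept: float  # AU
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0 or not math.isfinite(self.slope):
            raise ValueError("standard curve slope must be positive")


def fit_standard_curve(concentrations_um: Sequence[float],
                       absorbances: Sequence[float]) -> StandardCurve:
    """Least-squares line through a serial-dilution calibration series."""
    c = np.asarray(concentrations_um, float)
    a = np.asarray(absorbances, float)
    if c.size < 4:
        raise ValueError("standard curve needs >= 4 dilution points")
    slope, intercept = np.polyfit(c, a, 1)
    pred = slope * c + intercept
    ss_res = float(np.sum((a - pred) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return StandardCurve(slope=float(slope), intercept=float(intercept), r_squared=r2)


def absorbance_to_concentration(absorbance, curve: StandardCurve):
    """Invert the standard curve; negative concentrations clip to 0 with a warning."""
    a = np.asarray(absorbance, float)
    conc = (a - curve.intercept) / curve.slope
    if np.any(conc < 0):
        warnings.warn("absorbance below the curve intercept; clipping to 0 uM")
        conc = np.clip(conc, 0.0, None)
    return conc if conc.ndim else float(conc)


def correct_sampling_dilution(measured_conc: Sequence[float],
                              sample_volume_ml: float = 0.2,
                              total_volume_ml: float = 20.0) -> np.ndarray:
    """Correct serial-sampling dilution of a release medium.

    At each timepoint ``sample_volume_ml`` of medium is withdrawn and
    replaced with fresh buffer, so later measurements under-read the
    cumulative release.  The corrected concentration adds back the
    analyte removed at all earlier samplings::

        C_corr[k] = C_meas[k] + (v_s / v_tot) * sum_{j<k} C_meas[j]
    """
    if not 0 < sample_volume_ml < total_volume_ml:
        raise ValueError("need 0 < sample_volume < total_volume")
    c = np.asarray(measured_conc, float)
    frac = sample_volume_ml / total_volume_ml
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return c + frac * prior


def vesicle_assay_efficiency(records: pd.DataFrame,
                             initial_conc_um: float,
                             curve: StandardCurve,
                             sample_volume_ml: float = 0.2,
                             total_volume_ml: float = 20.0) -> pd.DataFrame:
    """Per-condition uptake time course from raw absorbance records.

    ``records`` needs columns ``time_min, abs550, condition, replicate``.
    Returns tidy rows ``condition, time_min, efficiency_pct_mean,
    efficiency_pct_sd, n`` after standard-curve inversion and cumulative
    sampling-dilution correction (applied per replicate series).
    """
    required = {"time_min", "abs550", "condition", "replicate"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    rows = []
    for (cond, rep), grp in records.groupby(["condition", "replicate"]):
        grp = grp.sort_values("time_min")
        conc = absorbance_to_concentration(grp["abs550"].to_numpy(), curve)
        conc = correct_sampling_dilution(conc, sample_volume_ml, total_volume_ml)
        for t, c in zip(grp["time_min"], conc):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                eff = transport_efficiency(initial_conc_um, float(c))
            rows.append({"condition": cond, "time_min": t, "replicate": rep,
                         "efficiency_pct": eff})
    tidy = pd.DataFrame(rows)
    out = (tidy.groupby(["condition", "time_min"])["efficiency_pct"]
           .agg(efficiency_pct_mean="mean",
                efficiency_pct_sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                n="count")
           .reset_index())
    return out
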