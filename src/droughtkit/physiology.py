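"""Physiological drought-stress indices from raw spectrophotometric assays.

Six leaf indices are covered, each with the formula conventionally used for
its wet-chemistry protocol:

* chloroplast pigment content (Chl a + Chl b + carotenoid, ethanol extraction,
  Arnon-type equations at 665/649/470 nm),
* relative electrical conductivity (REC, electrolyte-leakage ratio),
* superoxide dismutase activity (SOD, NBT-photoreduction inhibition;
  one unit = 50 % inhibition),
* malondialdehyde content (MDA, thiobarbituric-acid reaction at
  450/532/600 nm),
* soluble protein (Coomassie G-250, BSA standard curve),
* free proline (acid-ninhydrin, proline standard curve).

All operations consume blank-corrected absorbances; blank handling is the
caller's responsibility because it differs per protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class AssayValidationError(ValueError):
    """Raised when a raw assay record violates its physical invariants."""


# ---------------------------------------------------------------------------
# Assay records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChlAssay:
    """Ethanol-extract pigment assay.

    Absorbances at 665, 649 and 470 nm; fresh weight in g; total extract
    volume in mL; dilution is the fold-dilution applied before reading.
    """

    a665: float
    a649: float
    a470: float
    fresh_weight: float
    extract_volume: float
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a665, self.a649, self.a470) < 0:
            raise AssayValidationError("absorbances must be >= 0")
        if self.fresh_weight <= 0:
            raise AssayValidationError("fresh_weight must be > 0")
        if self.extract_volume <= 0:
            raise AssayValidationError("extract_volume must be > 0")
        if self.dilution < 1:
            raise AssayValidationError("dilution must be >= 1")


@dataclass(frozen=True)
class RECAssay:
    """Electrolyte-leakage conductivities in µS/cm: initial and after boiling."""

    conductivity_initial: float
    conductivity_boiled: float

    def __post_init__(self) -> None:
        if self.conductivity_boiled <= 0:
            raise AssayValidationError("boiled conductivity must be > 0")
        if self.conductivity_initial < 0:
            raise AssayValidationError("initial conductivity must be >= 0")
        if self.conductivity_initial > self.conductivity_boiled:
            raise AssayValidationError(
                "initial conductivity exceeds boiled conductivity"
            )


@dataclass(frozen=True)
class MDAAssay:
    """TBA-reaction absorbances at 450/532/600 nm, extract volume (mL), FW (g)."""

    d450: float
    d532: float
    d600: float
    extract_volume: float
    fresh_weight: float

    def __post_init__(self) -> None:
        if min(self.d450, self.d532, self.d600) < 0:
            raise AssayValidationError("absorbances must be >= 0")
        if self.extract_volume <= 0 or self.fresh_weight <= 0:
            raise AssayValidationError("volume and fresh weight must be > 0")


@dataclass(frozen=True)
class SPAssay:
    """Coomassie G-250 soluble-protein assay read at 595 nm."""

    a595: float
    total_extract_volume: float
    sample_volume: float
    fresh_weight: float

    def __post_init__(self) -> None:
        if self.a595 < 0:
            raise AssayValidationError("absorbance must be >= 0")
        if not (0 < self.sample_volume <= self.total_extract_volume):
            raise AssayValidationError(
                "need 0 < sample_volume <= total_extract_volume"
            )
        if self.fresh_weight <= 0:
            raise AssayValidationError("fresh_weight must be > 0")


@dataclass(frozen=True)
class SODAssay:
    """NBT-photoreduction assay: illuminated no-enzyme control vs sample."""

    a_illuminated_control: float
    a_sample: float
    enzyme_aliquot_volume: float
    total_extract_volume: float
    fresh_weight: float

    def __post_init__(self) -> None:
        if self.a_illuminated_control <= 0:
            raise AssayValidationError("illuminated control absorbance must be > 0")
        if self.a_sample < 0:
            raise AssayValidationError("sample absorbance must be >= 0")
        if min(
            self.enzyme_aliquot_volume,
            self.total_extract_volume,
            self.fresh_weight,
        ) <= 0:
            raise AssayValidationError("volumes and fresh weight must be > 0")


@dataclass(frozen=True)
class ProAssay:
    """Acid-ninhydrin proline assay read at 520 nm."""

    a520: float
    total_extract_volume: float
    sample_volume: float
    fresh_weight: float

    def __post_init__(self) -> None:
        if self.a520 < 0:
            raise AssayValidationError("absorbance must be >= 0")
        if not (0 < self.sample_volume <= self.total_extract_volume):
            raise AssayValidationError(
                "need 0 < sample_volume <= total_extract_volume"
            )
        if self.fresh_weight <= 0:
            raise AssayValidationError("fresh_weight must be > 0")


# ---------------------------------------------------------------------------
# Standard curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """Linear map absorbance -> analyte quantity: C = slope * A + intercept."""

    slope: float
    intercept: float
    r_squared: float
    analyte: str

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise AssayValidationError("standard-curve slope must be nonzero")
        if not (0 <= self.r_squared <= 1):
            raise AssayValidationError("r_squared must be in [0, 1]")

    def concentration(self, absorbance: float) -> float:
        return self.slope * absorbance + self.intercept


def fit_standard_curve(
    known_concentrations: Sequence[float],
    absorbances: Sequence[float],
    analyte: str,
) -> StandardCurve:
    """Ordinary least-squares calibration line mapping absorbance to quantity.

    Requires at least two points with non-constant absorbance.
    """
    conc = np.asarray(known_concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.shape != absb.shape or conc.size < 2:
        raise AssayValidationError("need >= 2 matching calibration points")
    if np.ptp(absb) == 0:
        raise AssayValidationError("calibration absorbances have zero variance")
    fit = stats.linregress(absb, conc)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        analyte=analyte,
    )


# Nominal calibration lines used by the synthetic generator (quantity in µg
# per cuvette; intercept zero so a zero reading means zero analyte).
DEFAULT_BSA_CURVE = StandardCurve(slope=100.0, intercept=0.0, r_squared=1.0, analyte="BSA")
DEFAULT_PRO_CURVE = StandardCurve(slope=50.0, intercept=0.0, r_squared=1.0, analyte="proline")


# ---------------------------------------------------------------------------
# Index computations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PigmentResult:
    """Pigment concentrations (mg/L) and total pigment content (mg/g FW).

    ``clamped`` flags that a raw Arnon-equation concentration came out
    negative (possible with noisy absorbances) and was clamped to zero.
    """

    chl_a: float
    chl_b: float
    carotenoid: float
    total_concentration: float
    pigment_content: float
    clamped: bool = False
    unit: str = field(default="mg g-1 FW", compare=False)


def compute_chlorophyll(assay: ChlAssay) -> PigmentResult:
    """Pigment content from 665/649/470 nm absorbances.

    Ca = 13.95*A665 - 6.88*A649
    Cb = 24.96*A649 - 7.32*A665
    Cx.c = (1000*A470 - 2.05*Ca - 114.8*Cb) / 245
    content (mg/g FW) = (Ca+Cb+Cx.c) * V_T * n / (FW * 1000)
    """
    ca = 13.95 * assay.a665 - 6.88 * assay.a649
    cb = 24.96 * assay.a649 - 7.32 * assay.a665
    cxc = (1000.0 * assay.a470 - 2.05 * ca - 114.8 * cb) / 245.0
    clamped = False
    if ca < 0:
        ca, clamped = 0.0, True
    if cb < 0:
        cb, clamped = 0.0, True
    if cxc < 0:
        cxc, clamped = 0.0, True
    total = ca + cb + cxc
    content = (total * assay.extract_volume * assay.dilution) / (
        assay.fresh_weight * 1000.0
    )
    return PigmentResult(
        chl_a=ca,
        chl_b=cb,
        carotenoid=cxc,
        total_concentration=total,
        pigment_content=content,
        clamped=clamped,
    )


def compute_rec(assay: RECAssay) -> float:
    """Relative electrical conductivity, percent: 100 * C1 / C2."""
    return 100.0 * assay.conductivity_initial / assay.conductivity_boiled


def compute_mda(assay: MDAAssay, *, as_nmol: bool = False) -> float:
    """MDA content: [6.452*(D532 - D600) - 0.56*D450] * V / (W * 1000).

    Returned in µmol/g FW by default; ``as_nmol`` multiplies by 1000 for
    reporting on the nmol/g scale that stress-physiology results are often
    quoted on.
    """
    value = (
        (6.452 * (assay.d532 - assay.d600) - 0.56 * assay.d450)
        * assay.extract_volume
        / (assay.fresh_weight * 1000.0)
    )
    return value * 1000.0 if as_nmol else value


def compute_sp(assay: SPAssay, curve: StandardCurve) -> float:
    """Soluble protein, mg/g FW: C(µg) * VT / (VS * W * 1000)."""
    if curve.analyte != "BSA":
        raise AssayValidationError(
            f"soluble protein requires a BSA curve, got {curve.analyte!r}"
        )
    c_ug = curve.concentration(assay.a595)
    return c_ug * assay.total_extract_volume / (
        assay.sample_volume * assay.fresh_weight * 1000.0
    )


def sod_inhibition(assay: SODAssay) -> float:
    """Fractional inhibition of NBT photoreduction, (A_ck - A_s) / A_ck."""
    return (assay.a_illuminated_control - assay.a_sample) / assay.a_illuminated_control


def compute_sod(assay: SODAssay) -> float:
    """SOD activity in U/g FW; one unit = 50 % inhibition of NBT reduction.

    activity = (inhibition / 0.5) * (V_total / V_aliquot) / FW
    """
    units_in_aliquot = sod_inhibition(assay) / 0.5
    return (
        units_in_aliquot
        * (assay.total_extract_volume / assay.enzyme_aliquot_volume)
        / assay.fresh_weight
    )


def compute_pro(assay: ProAssay, curve: StandardCurve) -> float:
    """Free proline, µg/g FW: Pro(µg) * VT / (VS * W)."""
    if curve.analyte != "proline":
        raise AssayValidationError(
            f"proline requires a proline curve, got {curve.analyte!r}"
        )
    pro_ug = curve.concentration(assay.a520)
    return pro_ug * assay.total_extract_volume / (
        assay.sample_volume * assay.fresh_weight
    )


# ---------------------------------------------------------------------------
# Time-course summaries
# ---------------------------------------------------------------------------

SUMMARY_MODES = (
    "value_at_final",
    "fold_change_final_vs_control",
    "mean_stress_over_control",
    "peak_fold_change",
)


def summarize_timecourse(values: Sequence[float], mode: str) -> float:
    """Reduce one cultivar x index time course to a scalar.

    The first entry is the unstressed control. Ratio modes divide by it and
    therefore require it to be nonzero.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("empty time course")
    if mode not in SUMMARY_MODES:
        raise ValueError(f"unknown summary mode {mode!r}")
    if mode == "value_at_final":
        return vals[-1]
    control = vals[0]
    if control == 0:
        raise ValueError("control value is zero; ratio summary undefined")
    if mode == "fold_change_final_vs_control":
        return vals[-1] / control
    if mode == "peak_fold_change":
        return max(abs(v / control) for v in vals[1:]) if len(vals) > 1 else 1.0
    # mean_stress_over_control
    if len(vals) == 1:
        return 1.0
    return (sum(vals[1:]) / (len(vals) - 1)) / control


# ---------------------------------------------------------------------------
# Tidy-table driver (used by the CLI and the synthetic round trip)
# ---------------------------------------------------------------------------

_ASSAY_UNITS = {
    "chl": "mg g-1 FW",
    "rec": "%",
    "sod": "U g-1 FW",
    "mda": "umol g-1 FW",
    "sp": "mg g-1 FW",
    "pro": "ug g-1 FW",
}

ASSAY_NAMES = tuple(_ASSAY_UNITS)


def compute_assay_table(
    assay_name: str,
    records: pd.DataFrame,
    curve: StandardCurve | None = None,
) -> pd.DataFrame:
    """Apply one index formula to a table of raw measurements.

    ``records`` carries one row per cultivar x day x replicate with the raw
    fields of the corresponding assay record; the result is a tidy table with
    columns (cultivar, day, replicate, index, value, unit).
    """
    if assay_name not in _ASSAY_UNITS:
        raise ValueError(f"unknown assay {assay_name!r}")
    values = []
    for row in records.itertuples(index=False):
        r = row._asdict()
        if assay_name == "chl":
            v = compute_chlorophyll(
                ChlAssay(
                    a665=r["a665"],
                    a649=r["a649"],
                    a470=r["a470"],
                    fresh_weight=r["fresh_weight"],
                    extract_volume=r["extract_volume"],
                    dilution=r.get("dilution", 1.0),
                )
            ).pigment_content
        elif assay_name == "rec":
            v = compute_rec(
                RECAssay(
                    conductivity_initial=r["conductivity_initial"],
                    conductivity_boiled=r["conductivity_boiled"],
                )
            )
        elif assay_name == "mda":
            v = compute_mda(
                MDAAssay(
                    d450=r["d450"],
                    d532=r["d532"],
                    d600=r["d600"],
                    extract_volume=r["extract_volume"],
                    fresh_weight=r["fresh_weight"],
                )
            )
        elif assay_name == "sod":
            v = compute_sod(
                SODAssay(
                    a_illuminated_control=r["a_illuminated_control"],
                    a_sample=r["a_sample"],
                    enzyme_aliquot_volume=r["enzyme_aliquot_volume"],
                    total_extract_volume=r["total_extract_volume"],
                    fresh_weight=r["fresh_weight"],
                )
            )
        elif assay_name == "sp":
            if curve is None:
                raise ValueError("soluble protein needs a standard curve")
            v = compute_sp(
                SPAssay(
                    a595=r["a595"],
                    total_extract_volume=r["total_extract_volume"],
                    sample_volume=r["sample_volume"],
                    fresh_weight=r["fresh_weight"],
                ),
                curve,
            )
        else:  # pro
            if curve is None:
                raise ValueError("proline needs a standard curve")
            v = compute_pro(
                ProAssay(
                    a520=r["a520"],
                    total_extract_volume=r["total_extract_volume"],
                    sample_volume=r["sample_volume"],
                    fresh_weight=r["fresh_weight"],
                ),
                curve,
            )
        values.append(v)
    out = records.loc[:, ["cultivar", "day", "replicate"]].copy()
    out["index"] = assay_name
    out["value"] = values
    out["unit"] = _ASSAY_UNITS[assay_name]
    return out
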