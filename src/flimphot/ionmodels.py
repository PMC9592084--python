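"""Ion-indicator calibration and Na+/K+-pump activation models.

Two small parametric models connect the photometry readouts to ion
physiology:

* **SBFI calibration** — SBFI fluorescence (790 nm excitation) is
  quenched by Na+ binding with a single-site isotherm of Kd = 26 mM.
  Writing f(x) = x / (Kd + x) for the bound fraction and ``a`` for the
  fractional fluorescence lost at Na+ saturation,

      F(na) = F_free * (1 - a * f(na))
      dF/F  = -a * (f(na) - f(na_rest)) / (1 - a * f(na_rest))

  referenced to the fluorescence at the resting [Na+] of 13 mM.  With
  a = 0.74 this inverts the mean peak dF/F of -25.6 % to a ~25 mM
  increase and -11.5 % (Ca2+ entry blocked) to ~8 mM.

* **Hill pump activation** — Na+/K+-pump turnover is cooperatively
  activated by intracellular Na+ with Hill coefficient ~3 (three
  transported Na+) and, for the alpha1beta1 isozyme, a half-activation
  K0.5 of ~13 mM, i.e. the pump rests near half activation:

      v/v_max = na^n / (na^n + k_half^n)

Transport stoichiometries (per cycle): the Na+/K+ pump exports 3 Na+
and imports 2 K+ per ATP; forward NCX exports 1 Ca2+ by importing
3 Na+; PMCA exports 1 Ca2+ per ATP; SERCA pumps 2 Ca2+ per ATP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SBFICalibration",
    "HillPump",
    "TransportStoichiometry",
    "dff_from_na",
    "na_from_dff",
    "hill_fraction",
    "fold_activation",
    "ncx_na_load",
    "atp_cost",
    "round_mm",
    "round_percent5",
    "round_fold_half",
]


@dataclass(frozen=True)
class SBFICalibration:
    """Single-site Na+ quench calibration of SBFI dF/F.

    kd : apparent Na+ dissociation constant, mM.
    na_rest : resting intracellular [Na+], mM (dF/F reference point).
    quench_amplitude_a : fraction of fluorescence lost at Na+ saturation
        relative to Na+-free fluorescence.
    """

    kd: float = 26.0
    na_rest: float = 13.0
    quench_amplitude_a: float = 0.74

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("kd must be > 0")
        if self.na_rest < 0:
            raise ValueError("na_rest must be >= 0")
        if not 0 < self.quench_amplitude_a <= 1:
            raise ValueError("quench_amplitude_a must be in (0, 1]")

    def bound_fraction(self, na) -> float | np.ndarray:
        na = np.asarray(na, dtype=float)
        out = na / (self.kd + na)
        return float(out) if out.ndim == 0 else out

    @property
    def max_quench(self) -> float:
        """dF/F limit as [Na+] -> infinity (most negative achievable)."""
        f0 = self.bound_fraction(self.na_rest)
        a = self.quench_amplitude_a
        return -a * (1.0 - f0) / (1.0 - a * f0)

    @property
    def max_brightening(self) -> float:
        """dF/F at [Na+] = 0 (largest positive achievable: full unquench)."""
        f0 = self.bound_fraction(self.na_rest)
        a = self.quench_amplitude_a
        return a * f0 / (1.0 - a * f0)


@dataclass(frozen=True)
class HillPump:
    """Hill model of Na+/K+-pump activation by intracellular Na+."""

    isozyme: str = "alpha1beta1"
    k_half: float = 13.0
    hill_n: float = 3.0

    def __post_init__(self) -> None:
        if not self.k_half > 0:
            raise ValueError("k_half must be > 0")
        if not self.hill_n > 0:
            raise ValueError("hill_n must be > 0")


@dataclass(frozen=True)
class TransportStoichiometry:
    """Ions moved per transporter cycle (all per 1 ATP except NCX,
    which is secondary active transport)."""

    na_per_ca_ncx: int = 3
    na_per_atp_nka: int = 3
    k_per_atp_nka: int = 2
    ca_per_atp_pmca: int = 1
    ca_per_atp_serca: int = 2

    def __post_init__(self) -> None:
        for name in (
            "na_per_ca_ncx",
            "na_per_atp_nka",
            "k_per_atp_nka",
            "ca_per_atp_pmca",
            "ca_per_atp_serca",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v}")


def dff_from_na(na, calib: SBFICalibration = SBFICalibration()):
    """SBFI dF/F at intracellular [Na+] ``na`` (mM), referenced to rest.

    Zero at ``na == na_rest`` and strictly decreasing in na.
    """
    na_arr = np.asarray(na, dtype=float)
    if np.any(na_arr < 0):
        raise ValueError("na must be >= 0")
    a = calib.quench_amplitude_a
    f = na_arr / (calib.kd + na_arr)
    f0 = calib.bound_fraction(calib.na_rest)
    out = -a * (f - f0) / (1.0 - a * f0)
    return float(out) if out.ndim == 0 else out


def na_from_dff(dff: float, calib: SBFICalibration = SBFICalibration()) -> float:
    """Invert the calibration: signed [Na+] change from rest (mM) given dF/F.

    Exact algebraic inversion.  Valid between the maximal quench
    (Na+ -> infinity, excluded) and the maximal brightening (Na+ = 0,
    included): quenches map to Na+ rises, brightenings to falls.
    """
    if dff > calib.max_brightening:
        raise ValueError(
            f"dff={dff} exceeds the maximal brightening "
            f"{calib.max_brightening:.4f} (reached at [Na+] = 0)"
        )
    if dff <= calib.max_quench:
        raise ValueError(
            f"dff={dff} is at or below the maximal quench {calib.max_quench:.4f}"
        )
    a = calib.quench_amplitude_a
    f0 = calib.bound_fraction(calib.na_rest)
    f = f0 - dff * (1.0 - a * f0) / a
    na = calib.kd * f / (1.0 - f)
    return float(na - calib.na_rest)


def hill_fraction(na, pump: HillPump = HillPump()):
    """Fractional pump activity (0-1) at intracellular [Na+] ``na`` (mM)."""
    na_arr = np.asarray(na, dtype=float)
    if np.any(na_arr < 0):
        raise ValueError("na must be >= 0")
    x = na_arr**pump.hill_n
    out = x / (x + pump.k_half**pump.hill_n)
    return float(out) if out.ndim == 0 else out


def fold_activation(
    na_base: float, na_peak: float, pump: HillPump = HillPump()
) -> float:
    """Ratio of pump activities at peak vs baseline [Na+]."""
    base = hill_fraction(na_base, pump)
    if base == 0:
        raise ValueError("pump activity at na_base is zero; fold undefined")
    return hill_fraction(na_peak, pump) / base


def ncx_na_load(
    ca_extruded, stoich: TransportStoichiometry = TransportStoichiometry()
):
    """Na+ imported by forward NCX while extruding ``ca_extruded`` Ca2+."""
    ca = np.asarray(ca_extruded, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca_extruded must be >= 0")
    out = stoich.na_per_ca_ncx * ca
    return float(out) if out.ndim == 0 else out


def atp_cost(
    na_extruded, stoich: TransportStoichiometry = TransportStoichiometry()
):
    """ATP consumed by the Na+/K+ pump to extrude ``na_extruded`` Na+."""
    na = np.asarray(na_extruded, dtype=float)
    if np.any(na < 0):
        raise ValueError("na_extruded must be >= 0")
    out = na / stoich.na_per_atp_nka
    return float(out) if out.ndim == 0 else out


# Reporting conventions matching the "~" precision of the source estimates:
# mM to the nearest integer, percent activity to the nearest 5 points,
# fold changes to the nearest 0.5.  Raw values are always kept alongside.

def round_mm(na_mm: float) -> int:
    return int(round(na_mm))


def round_percent5(percent: float) -> int:
    return int(5 * round(percent / 5))


def round_fold_half(fold: float) -> float:
    return 0.5 * round(fold / 0.5)
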