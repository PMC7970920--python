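"""Published reference values for the GDD quality-control study.

These are the printed study-level summaries used to parameterize synthetic
scenarios and worked examples:

* the 30 characteristic HPLC fingerprint peaks of GDD (batch-mean retention
  time, mean area, and their relative standard deviations across the ten
  production batches), with peak 13 as the RRT/RPA anchor;
* the coordination stoichiometries, equilibrium constants and thermodynamic
  parameters of the six Cu(II)-coordinating marker compounds;
* the HPLC calibration equations and validation metadata of the eight
  quantified markers.

The raw instrument data behind these summaries were never deposited, so the
synthetic generators treat the summaries as ground truth to emulate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FingerprintPeak",
    "FINGERPRINT_PEAKS",
    "ANCHOR_PEAK_ID",
    "ComplexParams",
    "COMPLEXATION",
    "CalibrationRef",
    "CALIBRATIONS",
    "STOCK_CONC_G_PER_ML",
]


@dataclass(frozen=True)
class FingerprintPeak:
    peak_id: int
    t_r: float        # mean retention time, min
    rrt_rsd: float    # % RSD of the relative retention time across batches
    area: float       # mean peak area, mV·s
    area_rsd: float   # % RSD of the relative peak area across batches


#: The 30 characteristic fingerprint peaks (batch means); peak 13 is the anchor.
FINGERPRINT_PEAKS: tuple[FingerprintPeak, ...] = (
    FingerprintPeak(1, 7.756, 0.56, 72.904, 10.39),
    FingerprintPeak(2, 8.143, 0.57, 59.030, 9.47),
    FingerprintPeak(3, 9.734, 0.54, 145.366, 10.08),
    FingerprintPeak(4, 11.964, 0.30, 117.960, 8.56),
    FingerprintPeak(5, 14.959, 0.29, 404.900, 8.87),
    FingerprintPeak(6, 15.900, 0.34, 450.606, 8.91),
    FingerprintPeak(7, 16.521, 0.25, 128.207, 7.53),
    # peak 8's printed area-RSD cell is ambiguous (run-on formatting);
    # a mid-range placeholder is used for synthetic dispersion only.
    FingerprintPeak(8, 17.707, 0.26, 72.247, 10.0),
    FingerprintPeak(9, 20.061, 0.28, 342.690, 7.49),
    FingerprintPeak(10, 20.312, 0.27, 636.449, 7.17),
    FingerprintPeak(11, 20.732, 0.26, 1206.278, 8.10),
    FingerprintPeak(12, 22.122, 0.27, 73.309, 10.63),
    FingerprintPeak(13, 22.770, 0.23, 273.065, 12.92),
    FingerprintPeak(14, 24.500, 0.17, 1023.162, 4.15),
    FingerprintPeak(15, 24.910, 0.21, 4522.499, 7.15),
    FingerprintPeak(16, 38.294, 0.19, 138.848, 7.55),
    FingerprintPeak(17, 38.701, 0.16, 183.776, 16.17),
    FingerprintPeak(18, 40.440, 0.09, 87.290, 18.8),
    FingerprintPeak(19, 42.297, 0.07, 234.678, 10.66),
    FingerprintPeak(20, 42.761, 0.08, 240.609, 7.20),
    FingerprintPeak(21, 43.714, 0.08, 212.670, 7.89),
    FingerprintPeak(22, 44.460, 0.06, 132.703, 8.46),
    FingerprintPeak(23, 44.853, 0.06, 142.171, 8.91),
    FingerprintPeak(24, 45.252, 0.04, 483.057, 8.01),
    FingerprintPeak(25, 46.901, 0.05, 226.967, 7.29),
    FingerprintPeak(26, 50.171, 0.06, 505.276, 7.72),
    FingerprintPeak(27, 50.522, 0.05, 156.973, 19.51),
    FingerprintPeak(28, 51.336, 0.07, 105.058, 7.11),
    FingerprintPeak(29, 52.295, 0.06, 413.034, 23.28),
    FingerprintPeak(30, 53.242, 0.04, 102.423, 10.00),
)

#: The designated RRT/RPA reference peak.
ANCHOR_PEAK_ID = 13


@dataclass(frozen=True)
class ComplexParams:
    """Coordination and thermodynamic parameters of one marker–Cu complex."""

    ligand_to_cu: tuple[int, int]  # reduced ligand:Cu stoichiometry
    K: float                       # equilibrium constant (reported ×10^7 scale)
    delta_H: float                 # kJ/mol
    delta_S: float                 # J·mol⁻¹·K⁻¹
    delta_G: float                 # kJ/mol (as reported, Gibbs relation at 298 K)

    @property
    def m(self) -> int:
        """Cu count per complex."""
        return self.ligand_to_cu[1]

    @property
    def n(self) -> int:
        """Ligand count per complex."""
        return self.ligand_to_cu[0]


#: Reported complexation parameters of the six Cu-coordinating markers.
COMPLEXATION: dict[str, ComplexParams] = {
    "quercetin":    ComplexParams((2, 1), 1.616e7, -11.683, -16.072, -6.894),
    "kaempferide":  ComplexParams((1, 1), 1.459e7, -17.132, -35.21, -6.641),
    "curcumin":     ComplexParams((2, 1), 7.094e7, -11.324, -2.567, -10.559),
    "rhein":        ComplexParams((1, 2), 9.063e7, -14.453, -11.03, -11.166),
    "chrysophanol": ComplexParams((1, 2), 7.263e7, -13.125, -8.41, -10.617),
    "emodin":       ComplexParams((1, 2), 1.451e7, -10.882, -14.28, -6.626),
}


@dataclass(frozen=True)
class CalibrationRef:
    """Published calibration equation and validation metadata of one marker.

    LOD/LOQ are carried as metadata only: the published LOD:LOQ ratios are not
    the ICH 3.3:10, so the noise-estimation procedure behind them is unknown
    and they are not recomputed.
    """

    slope: float            # area per (µg/ml)
    intercept: float        # area
    r: float
    linear_range: tuple[float, float]  # µg/ml
    lod: float              # µg/ml (metadata)
    loq: float              # µg/ml (metadata)


#: Published calibration curves of the eight quantified markers.
CALIBRATIONS: dict[str, CalibrationRef] = {
    "quercetin":    CalibrationRef(4710.0, 4.9947, 0.9994, (5.16, 51.56), 0.48, 1.67),
    "aloe-emodin":  CalibrationRef(3634.6, -0.4983, 0.9997, (2.60, 26.00), 0.27, 0.83),
    "rhein":        CalibrationRef(1486.2, -0.4860, 0.9995, (3.28, 32.78), 0.33, 1.10),
    "kaempferide":  CalibrationRef(3359.4, -2.9033, 0.9996, (2.90, 29.00), 0.31, 0.98),
    "curcumin":     CalibrationRef(1334.3, -4.7807, 0.9999, (4.09, 40.89), 0.41, 1.36),
    "emodin":       CalibrationRef(2820.5, -2.0968, 0.9998, (2.46, 24.56), 0.21, 0.70),
    "chrysophanol": CalibrationRef(2949.1, -2.5418, 0.9995, (3.42, 34.22), 0.36, 1.20),
    "physcion":     CalibrationRef(1031.5, -1.7041, 0.9992, (2.89, 28.89), 0.23, 0.79),
}

#: Stock preparation used to map µg/ml back to mg per g of freeze-dried powder.
STOCK_CONC_G_PER_ML = 0.035
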