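"""Published reference values for the Dongzhaigang mangrove system.

These constants are data, not computation: the historical area series, the
published per-station accretion rates, and the projected sea-level-rise
rate and loss tables for the Dongzhaigang National Nature Reserve (Haikou,
Hainan). They are used to cross-check the package's own arithmetic
(rates from levels, percentages from areas) and to seed literature rows in
reports.

Two total-area constants coexist: the 2019 remote-sensing estimate is
1842 hm², but every published loss area/percentage pair is simultaneously
consistent with a total of 1841 hm² (e.g. 489/1841 = 26.56 %), so 1841 is
the denominator used when reproducing the percentage block; the difference
is at most 0.01 percentage points.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "AREA_TIMESERIES_HM2", "LITERATURE_ACCRETION_CM_PER_YR",
    "MEASURED_ACCRETION_CM_PER_YR", "PRINTED_MEAN_RATES_MM_PER_YR",
    "PRINTED_LOSS_TABLE", "TOTAL_AREA_DERIVED_HM2", "TOTAL_AREA_2019_HM2",
    "OBSERVED_RSLR_MM_PER_YR", "area_series_frame",
]

#: Historical mangrove area (hm²) at Dongzhaigang, literature-compiled.
AREA_TIMESERIES_HM2 = [
    (1956, 3416.0),
    (1959, 3213.0),
    (1983, 1733.0),
    (1987, 1537.0),
    (1988, 1809.0),
    (1995, 1711.0),   # roughly constant since the 1990s (range 1575-1812)
    (2019, 1842.0),   # 2 m resolution remote-sensing estimate
]

#: Historical (1992-94) accretion rates at Linshi and Daoxue villages.
LITERATURE_ACCRETION_CM_PER_YR = {"LS": 0.41, "DX": 0.64}

#: CF-CS rates from the 2020 cores at Hegang village and Sanjiang farm.
MEASURED_ACCRETION_CM_PER_YR = {"HG": 0.53, "SJ": 0.40}

#: Observed relative SLR around Dongzhaigang, 1980-2018 (tide gauge + CMIP5).
OBSERVED_RSLR_MM_PER_YR = 4.6

#: Published mean RSLR rates (mm yr⁻¹), as printed (string keeps precision).
PRINTED_MEAN_RATES_MM_PER_YR = {
    ("RCP2.6", 2030): "7.2", ("RCP4.5", 2030): "7.2", ("RCP8.5", 2030): "7.2",
    ("RCP2.6", 2050): "6.89", ("RCP4.5", 2050): "7.33", ("RCP8.5", 2050): "8.0",
    ("RCP2.6", 2100): "6.84", ("RCP4.5", 2100): "7.89", ("RCP8.5", 2100): "10.1",
}

#: Published projected mangrove loss: mean and 17-83% ("likely") bounds.
#: (area_hm2, pct, (area_lo, area_hi), (pct_lo, pct_hi)); pct as printed.
PRINTED_LOSS_TABLE = {
    ("RCP2.6", 2030): (302, "16.40", (22, 312), ("1.20", "16.95")),
    ("RCP4.5", 2030): (302, "16.40", (22, 312), ("1.20", "16.95")),
    ("RCP8.5", 2030): (302, "16.40", (22, 314), ("1.20", "17.06")),
    ("RCP2.6", 2050): (308, "16.73", (22, 328), ("1.20", "17.82")),
    ("RCP4.5", 2050): (312, "16.95", (22, 330), ("1.20", "17.93")),
    ("RCP8.5", 2050): (317, "17.22", (298, 335), ("16.19", "18.20")),
    ("RCP2.6", 2100): (324, "17.60", (21, 571), ("1.14", "31.02")),
    ("RCP4.5", 2100): (489, "26.56", (298, 750), ("16.19", "40.74")),
    ("RCP8.5", 2100): (589, "31.99", (334, 934), ("18.14", "50.73")),
}

#: Denominator consistent with every published area/percentage pair.
TOTAL_AREA_DERIVED_HM2 = 1841.0
#: Total area printed for 2019.
TOTAL_AREA_2019_HM2 = 1842.0


def printed_tolerance(printed: str) -> float:
    """Half a unit in the last printed decimal place."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return 0.5 * 10.0 ** (-decimals)


def area_series_frame() -> pd.DataFrame:
    """Literature area series as a tidy frame (year, area_hm2, source)."""
    df = pd.DataFrame(AREA_TIMESERIES_HM2, columns=["year", "area_hm2"])
    df["source"] = "literature"
    return df
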