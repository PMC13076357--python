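"""Published reference values for the Asian-elephant blood cohort.

These constants are inputs for worked examples and cross-checks: the
longitudinal sampling table of the repeatedly sampled captive elephants
(chronological ages at first and last sampling with the interval the
original report printed for each individual) and the headline accuracy
figures of the blood epigenetic clock.

Note that for individual 15 the printed interval (4.46 y) disagrees with
the difference of the printed ages (31.78 - 30.34 = 1.44 y); pipelines
here always recompute intervals from ages and flag such inconsistencies
(see :func:`methclock.longitudinal.check_interval_consistency`).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ELEPHANT_LONGITUDINAL_TABLE", "ELEPHANT_CLOCK_MAE_YEARS",
           "ELEPHANT_MAX_LIFESPAN_YEARS", "elephant_longitudinal_table"]

#: headline clock accuracy of the published Asian-elephant blood clock
ELEPHANT_CLOCK_MAE_YEARS = 4.82
#: maximum recorded lifespan used for the relative-error denominator
ELEPHANT_MAX_LIFESPAN_YEARS = 79.6

# individual_id, sex, age at first sampling, age at last sampling,
# interval as printed (years)
_LONGITUDINAL_ROWS = [
    (10, "F", 6.46, 7.93, 1.47),
    (11, "F", 8.95, 10.48, 1.53),
    (12, "F", 10.78, 12.24, 1.46),
    (13, "M", 17.64, 19.19, 1.55),
    (14, "F", 20.22, 21.75, 1.53),
    (15, "F", 30.34, 31.78, 4.46),
    (19, "M", 0.25, 3.64, 3.39),
    (20, "F", 7.90, 13.04, 5.14),
    (21, "M", 6.59, 12.00, 5.41),
    (22, "F", 6.46, 12.96, 6.50),
    (23, "F", 10.20, 15.79, 5.59),
    (24, "F", 16.39, 19.27, 2.78),
    (25, "F", 28.25, 41.67, 13.42),
    (26, "F", 29.06, 42.48, 13.22),
    (27, "F", 31.75, 43.90, 12.15),
    (28, "F", 38.35, 52.95, 14.60),
    (29, "F", 32.47, 46.38, 13.91),
]

ELEPHANT_LONGITUDINAL_TABLE = pd.DataFrame(
    _LONGITUDINAL_ROWS,
    columns=["individual_id", "sex", "age_first", "age_last",
             "interval_reported"],
)


def elephant_longitudinal_table() -> pd.DataFrame:
    """A fresh copy of the published first/last sampling-age table."""
    return ELEPHANT_LONGITUDINAL_TABLE.copy()
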