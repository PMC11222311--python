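"""Published summary counts used as validation inputs.

Contingency counts from a MIMIC-IV-derived cohort of 1,951 diabetic
patients who underwent coronary artery bypass grafting, 180 of whom
developed postoperative delirium. Rows are (non-delirium, delirium);
columns follow the listed exposure levels. These printed counts are inputs
for re-running the contingency-table and unadjusted logistic machinery;
they are not outputs of this package.
"""

from __future__ import annotations

import numpy as np

N_COHORT = 1951
N_POD = 180

#: exposure -> (levels, reference level, 2 x c counts [non-POD; POD])
CONTINGENCY_COUNTS = {
    "baseline": (("no", "mild", "severe"), "no",
                 np.array([[462, 1074, 235], [48, 95, 37]])),
    "mbg": (("no", "mild", "severe"), "no",
            np.array([[885, 838, 48], [79, 84, 17]])),
    "lage": (("low", "high"), "low", np.array([[1193, 578], [99, 81]])),
    "gli": (("low", "high"), "low", np.array([[912, 859], [63, 117]])),
    "mag": (("low", "high"), "low", np.array([[919, 852], [56, 124]])),
    "mage": (("low", "high"), "low", np.array([[890, 881], [85, 95]])),
    "class": ((1, 2, 3, 4), 1,
              np.array([[1570, 116, 19, 66], [141, 10, 7, 22]])),
}

#: Reported class shares of the 4-class trajectory solution (fractions).
CLASS_SHARES = (0.877, 0.0646, 0.0133, 0.0451)
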