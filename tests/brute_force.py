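"""Independent brute-force implementation of the CHE statistic, for oracle
tests.  Plain loops and scalar math, no shared code with the package beyond
numpy means (same summation order as the implementation's reference group).
"""

import math

import numpy as np


def bf_decompose(frame, beta, window, thresholds):
    """Loop-based CHE decomposition of an annualized internal-name frame.

    Returns (poverty_line_value, n_reference, rows) where rows is a list of
    dicts with se, pc, substituted, oop, flags per household.
    """
    records = frame.to_dict("records")
    oop_cols = ["oop_consultation", "oop_hospitalization", "oop_medicines",
                "oop_diagnostics", "oop_transport"]
    shares = []
    for r in records:
        if r["expenditure_total"] > 0:
            shares.append(r["expenditure_food"] / r["expenditure_total"])
        else:
            shares.append(None)
    valid = sorted(s for s in shares if s is not None)

    def nearest_rank(p):
        k = max(1, math.ceil(p / 100.0 * len(valid)))
        return valid[min(k, len(valid)) - 1]

    lo_val, hi_val = nearest_rank(window[0]), nearest_rank(window[1])
    ref_food = []
    n_ref = 0
    for r, s in zip(records, shares):
        if s is not None and lo_val <= s <= hi_val:
            n_ref += 1
            ref_food.append(r["expenditure_food"] / r["household_size"] ** beta)
    pl_value = float(np.mean(np.asarray(ref_food)))

    rows = []
    for r in records:
        se = pl_value * r["household_size"] ** beta
        the = r["expenditure_total"]
        food = r["expenditure_food"]
        if the - se >= 0:
            pc, subst = the - se, False
        else:
            pc, subst = the - food, True
        pc = max(pc, 0.0)
        oop = sum(r[c] for c in oop_cols)
        flags = {}
        for z in thresholds:
            if pc > 0:
                flags[z] = 1 if oop / pc >= z else 0
            else:
                flags[z] = 1 if oop > 0 else 0
        rows.append({"se": se, "pc": pc, "substituted": subst, "oop": oop,
                     "flags": flags})
    return pl_value, n_ref, rows
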