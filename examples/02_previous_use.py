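"""The composite previous-use statistic.

Previous use of a cell = sum over earlier visits of
(group size / days since the visit) x (track length during the visit):
recent, intensive use by a large group leaves the strongest trace, and the
trace decays as vegetation regrows.
"""

import pandas as pd

from gorillaspace import UsageLedger

visits = pd.DataFrame(
    [("Kyagurilo", 3, 4, "2012-10-01", 100.0),
     ("Kyagurilo", 3, 4, "2012-10-04", 50.0),
     ("Mubare",    3, 4, "2012-10-03", 420.0)],
    columns=["group", "cell_i", "cell_j", "date", "distance_m"])
sizes = pd.DataFrame(
    [("Kyagurilo", 2012, 10, 10), ("Mubare", 2012, 10, 6)],
    columns=["group", "year", "month", "size"])
ledger = UsageLedger(visits, sizes)

ref = "2012-10-06"
own = ledger.previous_use("Kyagurilo", (3, 4), ref)
nbr = ledger.neighbour_previous_use("Kyagurilo", (3, 4), ref)
print(f"previous use of cell (3,4) by Kyagurilo on {ref}: {own:.1f}")
print("  = 10/5 x 100  (five days ago)  +  10/2 x 50  (two days ago)")
print(f"previous use by its neighbours (here: Mubare): {nbr:.1f}")
print("  = 6/3 x 420   (three days ago)")
print("Units are individuals x metres / day: recent heavy use scores high.")
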