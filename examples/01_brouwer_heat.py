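"""Heat production and RQ from one day of chamber gas exchange.

Builds a constant-rate 24 h gas trace for one sow, integrates it, and
applies the Brouwer equation.
"""

from datetime import datetime, timedelta

import numpy as np

from sowcal import GasExchangeRecord, State, brouwer_thp, integrate_gas_day, respiratory_quotient

start = datetime(2024, 1, 1, 8, 0)
flow = 500.0  # chamber exhaust, L/min

# a 213 kg sow consuming ~47 L O2/h with RQ 0.97 (fed state):
# differential fractions of chamber exhaust
vo2_per_min, rq = 0.78, 0.97
records = [
    GasExchangeRecord(
        "S1", start + timedelta(minutes=int(m)),
        o2_conc=vo2_per_min / flow,
        co2_conc=rq * vo2_per_min / flow,
        ch4_conc=0.002 / flow,
        flow_l_min=flow,
        state=State.FED,
    )
    for m in np.arange(0, 1441, 5)
]

volumes = integrate_gas_day(records, (start, start + timedelta(minutes=1441)))
thp = brouwer_thp(volumes.vo2_l, volumes.vco2_l, volumes.vch4_l, urinary_n_g=2.8)

print(f"VO2  = {volumes.vo2_l:8.1f} L/d")
print(f"VCO2 = {volumes.vco2_l:8.1f} L/d")
print(f"RQ   = {respiratory_quotient(volumes.vo2_l, volumes.vco2_l):8.2f}")
print(f"THP  = {thp / 1000:8.2f} MJ/d")
# THP is the sow's whole-body heat output; dividing by BW^0.75 would put it
# on the metabolic-weight scale used for comparing animals of unequal size.
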