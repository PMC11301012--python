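"""Reduce a raw home-BP stream to per-period 14-day averages.

A participant measured twice one morning (only the first counts), once after
midnight (which belongs to the previous day's evening), and on two further
mornings.
"""

from datetime import datetime

from hbpnotify import BPMeasurement, period_averages

stream = [
    BPMeasurement("demo", datetime(2014, 3, 1, 6, 50), 182, 109),
    BPMeasurement("demo", datetime(2014, 3, 1, 7, 40), 150, 92),   # same morning: ignored
    BPMeasurement("demo", datetime(2014, 3, 2, 2, 10), 171, 104),  # evening of Mar 1
    BPMeasurement("demo", datetime(2014, 3, 2, 6, 45), 188, 113),
    BPMeasurement("demo", datetime(2014, 3, 3, 7, 5), 185, 111),
]

for avg in period_averages(stream):
    if avg.n_used:
        print(f"{avg.period:>8}: {avg.mean_sbp:6.1f}/{avg.mean_dbp:5.1f} mmHg from {avg.n_used} readings")
    else:
        print(f"{avg.period:>8}: no readings")

print(
    "\nThe morning average uses one reading per day (first-of-period rule); "
    "the 02:10 reading counted toward the previous evening."
)
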