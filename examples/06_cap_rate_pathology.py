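"""CAP-rate pathology scoring on epoch labels.

The CAP rate is the percentage of scored epochs that are not wake (S0) or
REM; a rate strictly above 30% flags the recording as pathological sleep
instability.  The first block reproduces a published-scale count mix; the
second shows the flag flipping across the threshold.
"""

from capscan import cap_rate

labels = ["SLEEP-REM"] * 2335 + ["SLEEP-S0"] * 2141 + ["CAP"] * (19590 - 2335 - 2141)
rate, pathological = cap_rate(labels)
print(f"{len(labels)} epochs, {labels.count('CAP')} CAP epochs")
print(f"CAP rate {rate:.2f}% -> pathological: {pathological}")

for pct in (25, 30, 31, 50):
    mix = ["CAP"] * pct + ["SLEEP-REM"] * (100 - pct)
    rate, pathological = cap_rate(mix)
    print(f"  {pct:3d}% CAP epochs -> rate {rate:5.1f}%, pathological: {pathological}")
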