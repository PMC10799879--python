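"""Classify ICD codes into outcome components and build the combined outcome.

Suicide-related codes (one regex family) mean *suicide* on a death record
and *attempt* on a clinical record; overdose codes are clinical-only. The
combined outcome takes, per patient and study window: any suicide death,
else the earliest attempt, else the earliest overdose.
"""

import pandas as pd

from riskpipe import build_combined_outcome, classify_code

for code, system, context in [("T14.91", "ICD10", "death-cause"),
                              ("E9509", "ICD9", "clinical"),
                              ("T40.2X1A", "ICD10", "clinical"),
                              ("J45.909", "ICD10", "clinical")]:
    print(f"{code:10s} ({system}, {context:11s}) -> "
          f"{classify_code(code, system, context)}")

events = pd.DataFrame({
    "patient_id": [7, 7, 7],
    "date": pd.to_datetime(["2010-04-11", "2011-05-15", "2009-08-02"]),
    "component": ["attempt", "suicide", "overdose"],
})
label = build_combined_outcome(events, ("2000-01-01", "2020-01-01"))
print(f"\npatient 7 combined outcome: {label.component} on {label.event_date} "
      f"(rule: {label.rule_applied})")
print("the suicide death wins even though the attempt and overdose came first —"
      "\npriority is suicide > attempt > overdose, and each patient counts once")
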