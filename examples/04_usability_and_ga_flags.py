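"""Score usability questionnaires and apply geriatric-assessment change flags.

SUS (System Usability Scale): ten items rated 1-5; odd items are
positively worded, even items negatively; scores run 0-100 with 68 the
conventional adequacy cutoff.  GA change flags apply prespecified
week-12 vs baseline thresholds per instrument.
"""

from remowear import ga_change_flags, sus_score

# three example respondents
for label, items in [
    ("enthusiast", [5, 1, 5, 1, 5, 1, 5, 1, 5, 1]),
    ("neutral", [3] * 10),
    ("mixed", [4, 2, 4, 1, 5, 2, 4, 2, 3, 2]),
]:
    s = sus_score(items)
    verdict = "adequate" if s >= 68 else "below cutoff"
    print(f"SUS {label:11s}: {s:5.1f}  ({verdict})")

baseline = {"g8": 14, "carg": 5, "cirsg": 3, "g8_srh": 2, "fact_g": 92}
week12 = {"g8": 13, "carg": 6, "cirsg": 3, "g8_srh": 2, "fact_g": 89.5}
change = ga_change_flags(baseline, week12)
print(f"\nGA decline flags: {sorted(change.flags)}")
# g8_decline fires (14 -> 13, decline >= 1); carg_increase fires
# (5 -> 6, increase >= 1); FACT-G dropped 2.5 <= 3, so no flag.
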