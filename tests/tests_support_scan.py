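"""Independent brute-force oracle for the schedule run-length constraint.

Kept separate from the implementation on purpose: it re-derives the
"no more than 2 consecutive stimulations of the same hand with the same
sensory cue" scan from the trial rows alone.
"""

import pandas as pd


def scan_max_run(df: pd.DataFrame) -> int:
    events = []
    for _, r in df.iterrows():
        keys = set()
        if r["tactile_side"] != "none":
            keys.add((r["tactile_side"], "tactile"))
        if r["auditory_side"] != "none":
            keys.add((r["auditory_side"], "auditory"))
        events.append(keys)
    best = 0
    for key in {k for e in events for k in e}:
        run = 0
        for e in events:
            run = run + 1 if key in e else 0
            best = max(best, run)
    return best
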