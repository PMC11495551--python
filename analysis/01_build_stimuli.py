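#!/usr/bin/env python
"""Build the artificial-grammar stimulus lists and one neonate session timeline.

Writes the four counterbalanced lists' composition and the session's
BIDS-style event table under results/stimuli/, and prints the design
arithmetic (triplet/trial/phase durations) the rest of the analysis relies on.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nadnirs import stimuli as st

OUT = Path(__file__).resolve().parents[1] / "results" / "stimuli"
SEED = 1


def main():
    rng = np.random.default_rng(SEED)
    lists = st.build_stimulus_lists(rng)
    rows = []
    for sl in lists:
        for role, trips in (("standard", sl.standard), ("correct", sl.correct),
                            ("incorrect", sl.incorrect)):
            for t in trips:
                rows.append({"list_id": sl.list_id, "grammar_family":
                             sl.grammar_family, "familiar_half": sl.familiar_half,
                             "role": role, "grammar_id": t.grammar_id,
                             "stim": t.spec_string()})
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "stimulus_lists.tsv", sep="\t", index=False)

    schedule = st.schedule_session("neonate", lists[0], rng)
    st.write_session(schedule, OUT / "session_list1", seed=SEED, write_audio=False)

    learn = [p for p in schedule.phases if p[0] == "Learning"][0]
    test = [p for p in schedule.phases if p[0] == "Test"][0]
    targets = schedule.target_trials()
    print(f"built {len(lists)} stimulus lists "
          f"({sum(1 for r in rows if r['role'] == 'standard')} standard triplets total)")
    print(f"triplet duration {st.TRIPLET_DURATION} s; target trial "
          f"{st.TARGET_TRIAL_DURATION} s")
    print(f"learning phase {learn[2]:.1f} s (60 triplets); test phase "
          f"{test[2]:.1f} s with {len(targets)} target trials "
          f"(10 correct + 10 incorrect)")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
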