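"""Simulate a felid-like locus along the lineage tree.

Evolves a (GAA)12 compound locus down the eight-lineage felid topology
under the default slippage/point/deletion regime, plus a second run with an
elevated large-deletion rate on a separate clade to emulate sudden locus
death.  Writes tip FASTA, event logs and the ground-truth death states.
"""

import argparse
import json
from pathlib import Path

from msatlife import lineage_stats as ls
from msatlife import repeat_core as rc
from msatlife import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results"

LEFT_FLANK = "ACGTTGCAACGGTACGATCCAGGTTACAGTTA"
RIGHT_FLANK = "TTGACCAGTACGGATTACAGGCATTCAGCCTA"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    OUT.mkdir(exist_ok=True)
    root = (LEFT_FLANK, "GAA" * 12, RIGHT_FLANK)

    # baseline regime down the felid lineage topology
    params = sd.SimParams(seed=args.seed)
    tips, log = sd.simulate_locus(ls.FELID_LINEAGE_TREE, root, params)
    sd.tips_to_fasta(tips, locus="ptia_like", path=OUT / "sim_tips.fa")
    (OUT / "sim_events.json").write_text(
        json.dumps(log.to_records(), indent=2) + "\n"
    )
    assert sd.replay(ls.FELID_LINEAGE_TREE, root, log) == tips

    # elevated-deletion clade vs control
    star = "(" + ",".join(f"t{i}:1" for i in range(16)) + ");"
    tips_hi, _ = sd.simulate_locus(
        star, root, sd.SimParams(large_del_rate=5.0, seed=args.seed + 1)
    )
    sd.tips_to_fasta(tips_hi, locus="ptia_like", path=OUT / "sim_deletion_clade.fa")

    states = {
        name: (
            "dead"
            if rc.longest_pure_run(region, "GAA") <= 1
            else "alive"
        )
        for name, (_, region, _) in {**tips, **tips_hi}.items()
    }
    (OUT / "sim_true_states.json").write_text(
        json.dumps(states, indent=2, sort_keys=True) + "\n"
    )
    n_dead = sum(s == "dead" for s in states.values())
    print(
        f"simulated {len(tips)} lineage tips (events: {len(log.events)}) "
        f"and a 16-tip elevated-deletion clade; {n_dead} tip(s) dead in total"
    )


if __name__ == "__main__":
    main()
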