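#!/usr/bin/env python
"""Generate the default synthetic study cohort and recordings.

Writes the full fixture set (cohort table, one 52-channel CSV per subject,
ground truth, manifest) under scratch/sim/ — recordings are bulky, so they
live outside results/.  Prints the cohort structure that downstream stages
assume: 45 SCZ / 26 MDD / 22 BIP / 51 HC with a 37/56 pooled FH+/FH- split.
"""

from collections import Counter
from pathlib import Path

from nirsvft.config import SimulationConfig
from nirsvft.io import write_fixture_set
from nirsvft.synthgen import generate_study

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sim"
SEED = 2017


def main() -> None:
    config = SimulationConfig()
    config.seed = SEED
    cohort, recordings = generate_study(config)
    manifest = write_fixture_set(cohort, recordings, OUT, config=config)

    print(f"simulated {manifest['n_subjects']} subjects -> {OUT}")
    print("diagnoses:", dict(Counter(s.diagnosis for s in cohort)))
    fh = Counter((s.diagnosis, s.fh_any_psychiatric) for s in cohort
                 if s.diagnosis != "HC")
    n_pos = sum(v for (dx, f), v in fh.items() if f is True)
    n_neg = sum(v for (dx, f), v in fh.items() if f is False)
    print(f"family history (any psychiatric): {n_pos} FH+, {n_neg} FH-")
    n_corrupted = sum(
        bool(r.ground_truth["corrupted_channels"]) for r in recordings)
    print(f"recordings with at least one corrupted channel: {n_corrupted}")


if __name__ == "__main__":
    main()
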