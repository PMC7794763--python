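"""Simulate the factorial ERG cohort used by the downstream analyses.

2x2 design (genotype: control vs diabetic; treatment: vehicle vs
fenofibrate), 10 animals per cell, two eyes each, four flash strengths with
10 repeats at the dim flashes and 5 at the bright ones.  The injected
effects follow the study's structure: a 30% b-wave reduction and a 5 ms OP
delay confined to untreated diabetics, with partial rescue under treatment.

Raw sweeps are bulky, so they land under scratch/; the per-animal ground
truth (small) is copied to results/.
"""

from pathlib import Path

from ergkit.pipeline import _write_tsv
from ergkit.simulate import CellEffect, EffectSpec, SimParams, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "erg_cohort"
RESULTS = ROOT / "results" / "erg"
SEED = 20260922

DESIGN = {
    ("control", "vehicle"): 10,
    ("control", "fenofibrate"): 10,
    ("diabetic", "vehicle"): 10,
    ("diabetic", "fenofibrate"): 10,
}
PARAMS = SimParams(luminance_levels=(-2.0, -1.0, 0.0, 1.4))
EFFECTS = EffectSpec(
    cells={
        ("diabetic", "vehicle"): CellEffect(b_factor=0.70, op_delay_ms=5.0),
        ("diabetic", "fenofibrate"): CellEffect(b_factor=0.95, op_delay_ms=1.5),
    }
)


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    sweeps, truth = simulate_cohort(DESIGN, PARAMS, EFFECTS, seed=SEED)
    sweeps.to_csv(SCRATCH / "sweeps.csv", index=False, float_format="%.6g")
    _write_tsv(truth, RESULTS / "ground_truth.tsv")
    n_animals = truth["animal_id"].nunique()
    n_traces = len(sweeps.groupby(["animal_id", "eye", "luminance_log", "trial"]))
    print(f"simulated {n_animals} animals, {n_traces} sweeps "
          f"({len(sweeps)} samples) -> {SCRATCH / 'sweeps.csv'}")
    print(f"ground truth ({len(truth)} rows) -> {RESULTS / 'ground_truth.tsv'}")


if __name__ == "__main__":
    main()
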