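"""Generate the default synthetic tumour cohort used by the later steps.

Writes the six pipeline inputs (causal assignments, SGA observations,
expression, clinical, survival, ground truth) under results/cohort/.
"""

from pathlib import Path

from oncomodules.simulate import SyntheticCohortSpec, generate_cohort, write_cohort

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    spec = SyntheticCohortSpec(seed=SEED)
    cohort = generate_cohort(spec)
    write_cohort(cohort, OUT)
    n_planted = sum(len(i["drivers"]) for i in cohort.truth["pathways"].values())
    print(f"cohort: {spec.n_tumours} tumours, {spec.n_pathways} planted "
          f"pathways ({n_planted} drivers), "
          f"{len(cohort.assignments)} causal assignments "
          f"({cohort.assignments['posterior'].ge(0.7).mean():.0%} high-posterior)")
    print(f"censoring fraction: {1 - cohort.survival['event'].mean():.2f}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
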