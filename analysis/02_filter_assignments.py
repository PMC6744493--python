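"""Apply the four filtering standards to the raw causal assignments.

Reads results/cohort/, writes the significant assignments and a summary to
results/filtering/.  Reports how many planted drivers survive and whether
any passenger slips through.
"""

import json
from pathlib import Path

from oncomodules import io as omio
from oncomodules.filtering import FilterThresholds, apply_filters

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    assignments = omio.read_assignments(BASE / "cohort" / "assignments.tsv")
    observations = omio.read_observations(BASE / "cohort" / "observations.tsv")
    truth = omio.read_json(BASE / "cohort" / "truth.json")

    result = apply_filters(assignments, observations, FilterThresholds())
    out = BASE / "filtering"
    out.mkdir(parents=True, exist_ok=True)
    result.significant_assignments.to_csv(out / "significant.tsv", sep="\t",
                                          index=False)

    planted = {d for info in truth["pathways"].values() for d in info["drivers"]}
    passengers = set(truth["passengers"])
    found = result.significant_drivers
    summary = {
        "assignments_in": len(assignments),
        "above_posterior_floor": len(result.valid),
        "tumour_driver_calls": len(result.driver_calls),
        "significant_drivers": sorted(found),
        "significant_relationships": len(result.significant_relationships),
        "assignments_out": len(result.significant_assignments),
        "planted_driver_recall": len(found & planted) / len(planted),
        "passengers_leaked": sorted(found & passengers),
    }
    omio.write_json(summary, out / "summary.json")
    print(f"{summary['assignments_in']} assignments -> "
          f"{summary['above_posterior_floor']} above the posterior floor -> "
          f"{summary['assignments_out']} significant")
    print(f"significant drivers: {', '.join(summary['significant_drivers'])}")
    print(f"planted-driver recall {summary['planted_driver_recall']:.0%}; "
          f"passengers leaked: {summary['passengers_leaked'] or 'none'}")


if __name__ == "__main__":
    main()
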