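"""Run the complete pipeline with one call and inspect its reports.

Equivalent to `vesselmorph run --seed 5 --out example_run` on the
command line: generates the default population, measures, filters,
classifies, tests, and writes CSV/JSON reports with full accounting.
"""

import json
import warnings

from vesselmorph import PopulationSpec, RunConfig, run

config = RunConfig(
    mode="synthetic",
    population=PopulationSpec(n_group1=20, n_group2=10,
                              microns_per_pixel=0.1, image_size=500),
    master_seed=5,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run(config, "example_run")

print("manifest:", json.dumps(report.manifest, indent=1))
mwu = report.tests["area_ratio"]["mann_whitney"]
print(f"\narea-ratio test: U={mwu['U']:.1f}, p={mwu['p_two_sided']:.3g}")
print("range overlap:", report.tests["area_ratio"]["range_overlap"])
print("\nFiles in example_run/: truth.csv, measurements.csv,")
print("classifications.csv, summaries.json, tests.json, manifest.json.")
print("Re-running with the same config and seed reproduces them")
print("byte-for-byte (the manifest records the config hash).")
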