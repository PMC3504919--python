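"""The same pipeline driven through files and the command-line interface.

Writes a small synthetic scenario in the native text dialects (truth TSV,
Beagle-style .gprobs/.dose, annotation TSV, hotspot table), then reloads it
from disk and runs the evaluation — demonstrating that synthetic and real
data travel through identical code paths. The equivalent shell session is
shown at the bottom.
"""

import tempfile
from pathlib import Path

from iqspred import ImputationScenario, run_scenario
from iqspred.simulate import build_fixture, scaled_params

workdir = Path(tempfile.mkdtemp(prefix="iqspred_"))
train, test = build_fixture(scaled_params(0.25, seed=11))

scenarios = {}
for name, scn in (("train", train), ("test", test)):
    paths = scn.write_files(workdir, name)
    scenarios[name] = ImputationScenario.from_files(
        truth=paths["truth"], gprobs=paths["gprobs"],
        annotation=paths["annotation"], typed=paths["typed"],
        panel_counts=paths["panel_counts"], baf_truth=paths["baf_truth"],
        hotspots=paths["hotspots"],
    )
print(f"scenario files written to {workdir}")

report, _, _ = run_scenario(scenarios["train"], scenarios["test"])
print(report.to_json())

print("""
# shell equivalent:
#   iqspred simulate --preset small --seed 11 --out fixture/
#   iqspred run-scenario --config fixture/scenario.yaml
""")
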