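"""Train a nu-SVR to predict IQS from the 12-feature SNP descriptor.

Simulates a small platform-upgrade scenario, extracts the feature table and
true quality scores of the masked training SNPs, grid-searches nu by 10-fold
cross-validation, and reports the selected nu and the in-sample fit. The
fitted model is then serialized and reloaded to show that prediction
survives the round trip exactly.
"""

import tempfile
from pathlib import Path

import numpy as np

from iqspred import RegressionModel, fit_with_selection
from iqspred.simulate import build_fixture, scaled_params

train, _ = build_fixture(scaled_params(0.25, seed=11))
feats = train.feature_matrix()
scores = train.scores()
ok = scores["iqs"].notna()
X = feats[ok].to_numpy()
y = scores.loc[ok, "iqs"].to_numpy()
print(f"training SNPs with defined IQS: {len(y)}")

model = fit_with_selection(X, y, target_kind="IQS", seed=42)
pred = model.predict(X)
print(f"selected nu = {model.nu:.1f}; gamma = 1/12 (RBF kernel)")
print(f"in-sample MSE = {np.mean((pred - y) ** 2):.4f}")

model_path = Path(tempfile.mkdtemp(prefix="iqspred_")) / "model.json"
model.save(model_path)
reloaded = RegressionModel.load(model_path)
print("round-trip max prediction difference:",
      float(np.abs(reloaded.predict(X) - pred).max()))
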