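"""Run the whole analysis chain from one config and inspect the bundle.

Equivalent to `normevol run-all config.yaml` with `use_fixture: true`: writes
reaction-norm/coding/parsimony/Mk/BM tables plus a run report into out/.
"""

import tempfile
from pathlib import Path

from normevol import PipelineConfig, run_pipeline

out_dir = Path(tempfile.mkdtemp(prefix="normevol_"))
cfg = PipelineConfig(use_fixture=True, out_dir=str(out_dir))
results = run_pipeline(cfg, log=None)

print(results["report"])
print("files written:")
for p in sorted(out_dir.iterdir()):
    print(" ", p.name)
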