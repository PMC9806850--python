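"""Run the whole pipeline (simulate → preprocess → segment → backfit →
stats) from one config and print the generated report.

Equivalent CLI:  microstates pipeline --out-dir runs/demo --seed 3
"""

import tempfile
from pathlib import Path

from microstates import report, run_pipeline

config = {
    "seed": 3,
    "cohort": {"n_patients": 4, "n_controls": 4, "n_channels": 32,
               "duration_s": 30.0},
    "segment": {"k_individual": 5, "k_population": 6, "restarts": 8},
    "stats": {"tanova_permutations": 500},
}

out = Path(tempfile.mkdtemp()) / "demo_run"
run_pipeline(config, out)
print(report(out))
print(f"stage outputs and reproducibility manifest under: {out}")
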