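#!/usr/bin/env python
"""Carrier-only correlations between baseline clinical scores and change.

Mirrors the carriers-only arm of the analysis: the template and skeleton
are rebuilt from expansion carriers alone (template_subjects="carriers"),
and each baseline score (disease burden, SDMT, SWR, TMS, TFC, composite
UHDRS) is regressed voxelwise against each metric's baseline-minus-final
change, both one-sided directions, with age/sex/site as nuisance.

Writes results/correlations.tsv; run trees under scratch/runs/<cohort>_carriers/.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

from longtbss.pipeline import PipelineConfig, run_pipeline
from longtbss.simulate import simulate_cohort

sys.path.insert(0, str(Path(__file__).resolve().parent))
sim = import_module("01_simulate_cohorts")

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCORES = ("dbs", "sdmt", "swr", "tms", "tfc", "cuhdrs")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, spec in sim.scaled_specs().items():
        data = sim.SCRATCH / name
        simulate_cohort(spec, data)  # idempotent for a fixed seed
        cfg = PipelineConfig(
            dataset=str(data), outdir=str(ROOT / "scratch" / "runs" / f"{name}_carriers"),
            n_perm=500, seed=42, template_subjects="carriers",
            correlation_scores=SCORES,
        )
        res = run_pipeline(cfg)
        for (metric, score), pair in res.correlations.items():
            for res_dir in (pair.positive, pair.negative):
                if res_dir.n_significant == 0:
                    continue
                rows.append(
                    {
                        "cohort": name,
                        "metric": metric,
                        "score": score,
                        "association": res_dir.label,
                        "n_sig_voxels": res_dir.n_significant,
                        "min_pfwe": round(float(res_dir.pfwe.min()), 4),
                    }
                )
        print(f"{name}: correlations done "
              f"({len(res.correlations)} score x metric pairs tested)")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "correlations.tsv", sep="\t", index=False)
    print(f"\nsignificant associations -> {RESULTS / 'correlations.tsv'}")
    print(df.to_string(index=False) if len(df) else "(none significant at this scale)")


if __name__ == "__main__":
    main()
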