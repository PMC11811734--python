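#!/usr/bin/env python
"""X:AA estimator bias under the two dosage models.

Runs the full X:AA simulation (compensated and noncompensated models,
bulk and single-cell data, both estimators, threshold sweep) and writes
the per-replicate table plus its summary to results/.
"""

from pathlib import Path

from scxaa.pipeline import RunConfig, run
from scxaa.simulate import GeneratorConfig

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "xaa_sim"


def main() -> None:
    cfg = RunConfig(
        mode="xaa_sim",
        seed=SEED,
        n_replicates=250,
        generator=GeneratorConfig(
            n_autosomal_genes=5000, n_x_genes=508, n_cells=100
        ),
    )
    out = run(cfg, OUT)
    from scxaa.pipeline import read_tsv

    summary = read_tsv(out / "xaa_sim_summary.tsv")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
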