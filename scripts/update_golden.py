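"""Regenerate the golden-fixture reference outputs under tests/golden/.

The golden run is a fixed-seed synthetic study pushed through the full
pipeline; its manifest and report TSVs are stored in the repository and the
regression test requires byte-identical reproduction.
"""

import pathlib
import shutil
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from eqtlqc import pipeline, synth  # noqa: E402

GOLDEN_DIR = pathlib.Path(__file__).resolve().parents[1] / "tests" / "golden"

GOLDEN_SIM = synth.SimulationConfig(
    n_samples=24,
    n_snps=500,
    n_genes=160,
    n_true_eqtls=15,
    n_null_catalog=25,
    contaminated_samples=(("S004", "S019", 0.4),),
    seed=20,
)

GOLDEN_PIPE = pipeline.PipelineConfig(
    n_gw_pairs=600,
    seed=20,
    record_timing=False,
)


def run_golden(outdir) -> None:
    import dataclasses

    bundle = synth.simulate_all(GOLDEN_SIM)
    cfg = dataclasses.replace(GOLDEN_PIPE, outdir=str(outdir))
    pipeline.run(cfg, bundle=bundle)


if __name__ == "__main__":
    if GOLDEN_DIR.exists():
        shutil.rmtree(GOLDEN_DIR)
    GOLDEN_DIR.mkdir(parents=True)
    run_golden(GOLDEN_DIR)
    for p in sorted(GOLDEN_DIR.iterdir()):
        print(p.name, p.stat().st_size, "bytes")
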